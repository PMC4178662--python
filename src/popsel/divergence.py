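"""Lineage-specific divergence from a three-way alignment.

A site is called diverged on the focal lineage when both outgroups carry
the same base and the focal reference differs (unrooted parsimony with two
outgroups).  Any missing base in any of the three rows masks the site and
the 5 bp either side, guarding against spurious alignment around indels.
Only assessed sites enter numerators or denominators.  The outgroup
agreement base doubles as the ancestral state for spectrum polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import ClassMap, SiteClass
from .genome import GenomeBundle
from .variants import GT_MISSING, VariantTable

__all__ = ["TripletAlignment", "DivergenceCall", "DivergenceTable",
           "call_lineage_substitutions", "restrict_to_fixed", "gene_dnds",
           "class_divergence", "gene_index"]

_BASES = "ACGTN"
_CODE = {b: i for i, b in enumerate(_BASES)}
MISSING = 4


def encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, MISSING, dtype=np.uint8)
    for b, c in _CODE.items():
        out[arr == ord(b)] = c
    out[arr == ord("-")] = MISSING
    return out


def decode_seq(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


@dataclass
class TripletAlignment:
    """Per-contig aligned base codes for focal reference and two outgroups
    (reference-anchored columns; 4 = gap/N/missing)."""

    focal: dict[str, np.ndarray]
    outgroup1: dict[str, np.ndarray]
    outgroup2: dict[str, np.ndarray]

    def __post_init__(self):
        for contig in self.focal:
            a, b, c = (self.focal[contig], self.outgroup1[contig],
                       self.outgroup2[contig])
            if not (a.size == b.size == c.size):
                raise ValueError(f"alignment rows for {contig} have "
                                 "mismatched lengths")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for contig in self.focal:
                for name, row in (("focal", self.focal),
                                  ("outgroup1", self.outgroup1),
                                  ("outgroup2", self.outgroup2)):
                    fh.write(f">{contig}|{name}\n{decode_seq(row[contig])}\n")

    @classmethod
    def from_fasta(cls, path) -> "TripletAlignment":
        from Bio import SeqIO
        rows: dict[str, dict[str, np.ndarray]] = {
            "focal": {}, "outgroup1": {}, "outgroup2": {}}
        for rec in SeqIO.parse(str(path), "fasta"):
            contig, name = rec.id.rsplit("|", 1)
            rows[name][contig] = encode_seq(str(rec.seq))
        return cls(rows["focal"], rows["outgroup1"], rows["outgroup2"])


@dataclass
class DivergenceCall:
    """Genome-wide call result: per-contig boolean substitution and
    assessed masks, plus the polarization (ancestral-state) track."""

    substitution: dict[str, np.ndarray]
    assessed: dict[str, np.ndarray]
    ancestral: dict[str, np.ndarray]   # base code, 4 = unassignable

    def n_substitutions(self) -> int:
        return int(sum(m.sum() for m in self.substitution.values()))


def _dilate(mask: np.ndarray, flank: int) -> np.ndarray:
    out = mask.copy()
    for k in range(1, flank + 1):
        out[k:] |= mask[:-k]
        out[:-k] |= mask[k:]
    return out


def call_lineage_substitutions(aln: TripletAlignment,
                               flank: int = 5) -> DivergenceCall:
    """Parsimony substitution calls with the +-5 bp missing-data mask."""
    subs, assessed, anc = {}, {}, {}
    for contig in aln.focal:
        f = aln.focal[contig]
        o1 = aln.outgroup1[contig]
        o2 = aln.outgroup2[contig]
        missing = (f == MISSING) | (o1 == MISSING) | (o2 == MISSING)
        ok = ~_dilate(missing, flank)
        agree = (o1 == o2) & (o1 != MISSING)
        subs[contig] = ok & agree & (f != o1)
        assessed[contig] = ok
        a = np.full(f.size, MISSING, dtype=np.uint8)
        a[agree] = o1[agree]
        anc[contig] = a
    return DivergenceCall(subs, assessed, anc)


def restrict_to_fixed(call: DivergenceCall, table: VariantTable,
                      keep_mask: dict[str, np.ndarray],
                      min_chromosomes: int = 20) -> dict[str, np.ndarray]:
    """Keep substitutions where the population sample is monomorphic for
    the focal reference base: no non-reference genotype among non-missing
    samples, at least ``min_chromosomes`` non-missing chromosomes, and the
    site survives the genotype filters."""
    fixed = {}
    for contig, sub in call.substitution.items():
        d = table.arrays(contig)
        out = np.zeros(sub.size, dtype=bool)
        gt = d["gt"]
        called = gt != GT_MISSING
        mono_ref = ~np.any(gt > 0, axis=1)
        enough = 2 * called.sum(axis=1) >= min_chromosomes
        ok = mono_ref & enough & keep_mask[contig]
        pos = d["pos"]
        out[pos[ok]] = True
        fixed[contig] = sub & out
    return fixed


def gene_index(bundle: GenomeBundle) -> tuple[dict[str, np.ndarray],
                                              list[str]]:
    """Per-contig gene index painted over CDS positions (-1 outside CDS or
    where genes overlap ambiguously)."""
    genes = bundle.gene_ids
    gid = {g: i for i, g in enumerate(genes)}
    idx = {c: np.full(len(s), -1, dtype=np.int32)
           for c, s in bundle.sequences.items()}
    painted = {c: np.zeros(len(s), dtype=bool)
               for c, s in bundle.sequences.items()}
    for f in bundle.features:
        if f.ftype != "CDS":
            continue
        seg = idx[f.contig][f.start:f.end]
        conflict = painted[f.contig][f.start:f.end] & (seg != gid[f.gene_id])
        seg[:] = np.where(conflict, -1, gid[f.gene_id])
        painted[f.contig][f.start:f.end] = True
    return idx, genes


def class_divergence(call: DivergenceCall, class_map: ClassMap,
                     keep_mask: dict[str, np.ndarray] | None = None
                     ) -> pd.DataFrame:
    """Sites assessed and substitutions per site class."""
    rows = {c.name: {"sites_assessed": 0, "substitutions": 0}
            for c in SiteClass}
    for contig, assessed in call.assessed.items():
        cls = class_map.classes[contig]
        ok = assessed if keep_mask is None else assessed & keep_mask[contig]
        sub = call.substitution[contig] & ok
        for c in SiteClass:
            sel = cls == c
            rows[c.name]["sites_assessed"] += int((sel & ok).sum())
            rows[c.name]["substitutions"] += int((sel & sub).sum())
    df = pd.DataFrame(rows).T
    df.index.name = "site_class"
    with np.errstate(invalid="ignore"):
        df["rate"] = df["substitutions"] / df["sites_assessed"]
    return df


def gene_dnds(call: DivergenceCall, class_map: ClassMap,
              bundle: GenomeBundle,
              keep_mask: dict[str, np.ndarray] | None = None
              ) -> pd.DataFrame:
    """Count-based per-gene dN, dS and dN/dS.

    dN = 0-fold substitutions / assessed 0-fold sites; dS likewise at
    4-fold sites.  Genes without assessed sites are omitted; dN/dS is NaN
    (flagged, not zero) where dS = 0.
    """
    idx, genes = gene_index(bundle)
    n_genes = len(genes)
    acc = {k: np.zeros(n_genes) for k in
           ("N_sites", "S_sites", "N_subs", "S_subs")}
    for contig, assessed in call.assessed.items():
        cls = class_map.classes[contig]
        gi = idx[contig]
        ok = assessed if keep_mask is None else assessed & keep_mask[contig]
        ok = ok & (gi >= 0)
        sub = call.substitution[contig]
        zero = cls == SiteClass.zero_fold
        four = cls == SiteClass.four_fold
        for key, mask in (("N_sites", ok & zero), ("S_sites", ok & four),
                          ("N_subs", ok & zero & sub),
                          ("S_subs", ok & four & sub)):
            acc[key] += np.bincount(gi[mask], minlength=n_genes)
    df = pd.DataFrame({"gene_id": genes, **acc})
    df = df[(df["N_sites"] > 0) & (df["S_sites"] > 0)].copy()
    df["dN"] = df["N_subs"] / df["N_sites"]
    df["dS"] = df["S_subs"] / df["S_sites"]
    df["dN_dS"] = np.where(df["dS"] > 0, df["dN"] / df["dS"], np.nan)
    return df.reset_index(drop=True)
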