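"""Site classification: codon degeneracy, UTR/intron/intergenic classes,
intron-junction split, and the orthogonal CNS flag.

Every genomic site gets exactly one primary class.  Coding sites are classed
by degeneracy on the coding strand; following the analysis design, 2- and
3-fold degenerate positions (and any coding conflict) land in
``other_coding_excluded`` and are never analyzed, so selected/neutral coding
contrasts use clean 0-fold vs 4-fold sets only.  Intron sites within
``junction_bp`` (default 30) of either splice boundary are the junction
class.  Precedence for overlapping features: CDS > UTR > intron >
intergenic; genes that disagree about a coding site's degeneracy resolve to
the excluded class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .genome import GenomeBundle

__all__ = ["SiteClass", "CnsCategory", "ClassMap", "codon_degeneracy",
           "classify_sites", "ANALYZED_CLASSES"]

_BASES = "ACGT"


class SiteClass(IntEnum):
    intergenic = 0
    intron_internal = 1
    intron_junction = 2
    utr3 = 3
    utr5 = 4
    zero_fold = 5
    four_fold = 6
    other_coding_excluded = 7


class CnsCategory(IntEnum):
    none = 0
    intergenic_cns = 1
    intronic_cns = 2
    utr5_cns = 3
    utr3_cns = 4
    snc_cns = 5


ANALYZED_CLASSES = (SiteClass.zero_fold, SiteClass.four_fold,
                    SiteClass.utr5, SiteClass.utr3,
                    SiteClass.intron_internal, SiteClass.intron_junction,
                    SiteClass.intergenic)

_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


def _build_degeneracy_table() -> dict[tuple[str, int], int]:
    """fold label per (codon, position 0..2) over the 61 sense codons."""
    table: dict[tuple[str, int], int] = {}
    for codon, aa in _CODON_TABLE.items():
        for pos in range(3):
            syn = 0
            for b in _BASES:
                mutant = codon[:pos] + b + codon[pos + 1:]
                if mutant in _STOPS:
                    continue
                if _CODON_TABLE.get(mutant) == aa:
                    syn += 1
            # syn counts bases (incl. the current one) preserving the aa
            table[(codon, pos)] = {1: 0, 2: 2, 3: 3, 4: 4}[syn]
    return table


_DEGENERACY = _build_degeneracy_table()


def codon_degeneracy(codon: str, position: int) -> int | None:
    """Degeneracy label (0, 2, 3 or 4) of one codon position under the
    standard nuclear code; ``None`` for ambiguous or stop codons
    (unassessable, never guessed).

    ``position`` is 0-based within the codon.
    """
    codon = codon.upper()
    if position not in (0, 1, 2):
        raise ValueError("position must be 0, 1 or 2")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        return None
    if codon in _STOPS:
        return None
    return _DEGENERACY[(codon, position)]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ClassMap:
    """Per-contig site-class and CNS-category tracks (int8 arrays)."""

    classes: dict[str, np.ndarray]
    cns: dict[str, np.ndarray]

    def class_of(self, contig: str, pos: int) -> SiteClass:
        return SiteClass(int(self.classes[contig][pos]))

    def cns_of(self, contig: str, pos: int) -> CnsCategory:
        return CnsCategory(int(self.cns[contig][pos]))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {c.name: 0 for c in SiteClass}
        for arr in self.classes.values():
            binc = np.bincount(arr, minlength=len(SiteClass))
            for c in SiteClass:
                out[c.name] += int(binc[c])
        return out

    def cns_counts(self) -> dict[str, int]:
        out: dict[str, int] = {c.name: 0 for c in CnsCategory}
        for arr in self.cns.values():
            binc = np.bincount(arr, minlength=len(CnsCategory))
            for c in CnsCategory:
                out[c.name] += int(binc[c])
        return out

    def to_tsv(self, path) -> None:
        frames = []
        for contig, arr in self.classes.items():
            frames.append(pd.DataFrame({
                "contig": contig, "pos": np.arange(arr.size),
                "site_class": [SiteClass(v).name for v in arr],
                "cns_category": [CnsCategory(v).name
                                 for v in self.cns[contig]]}))
        pd.concat(frames).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClassMap":
        df = pd.read_csv(path, sep="\t")
        classes, cns = {}, {}
        for contig, sub in df.groupby("contig", sort=False):
            sub = sub.sort_values("pos")
            classes[str(contig)] = np.array(
                [SiteClass[v] for v in sub["site_class"]], dtype=np.int8)
            cns[str(contig)] = np.array(
                [CnsCategory[v] for v in sub["cns_category"]], dtype=np.int8)
        return cls(classes, cns)


def _gene_intron_intervals(bundle: GenomeBundle, gene_id: str
                           ) -> list[tuple[str, int, int]]:
    exons = sorted(bundle.features_of(gene_id, "exon"),
                   key=lambda f: f.start)
    if not exons:
        return []
    out = []
    for a, b in zip(exons, exons[1:]):
        if b.start > a.end:
            out.append((a.contig, a.end, b.start))
    return out


def classify_sites(bundle: GenomeBundle, junction_bp: int = 30) -> ClassMap:
    """Assign every site of every contig to one SiteClass, plus the CNS
    category flag from the interval set."""
    classes = {c: np.zeros(len(s), dtype=np.int8)
               for c, s in bundle.sequences.items()}
    # degeneracy paint buffer: -2 untouched, -1 conflict, else fold label
    deg = {c: np.full(len(s), -2, dtype=np.int8)
           for c, s in bundle.sequences.items()}

    # introns (internal, then junctions override their edges)
    for gene_id in bundle.gene_ids:
        for contig, start, end in _gene_intron_intervals(bundle, gene_id):
            arr = classes[contig]
            arr[start:end] = SiteClass.intron_internal
            j = min(junction_bp, end - start)
            arr[start:start + j] = SiteClass.intron_junction
            arr[max(end - j, start):end] = SiteClass.intron_junction

    # UTRs override introns
    for f in bundle.features:
        if f.ftype == "five_prime_UTR":
            classes[f.contig][f.start:f.end] = SiteClass.utr5
        elif f.ftype == "three_prime_UTR":
            classes[f.contig][f.start:f.end] = SiteClass.utr3

    # CDS degeneracy, painted with conflict detection
    for gene_id in bundle.gene_ids:
        segs = sorted(bundle.features_of(gene_id, "CDS"),
                      key=lambda f: f.start)
        if not segs:
            continue
        strand = segs[0].strand
        order = segs if strand == "+" else segs[::-1]
        cds = bundle.coding_sequence(gene_id)
        phase = order[0].phase
        # genomic position of each coding-strand base, transcription order
        positions: list[tuple[str, int]] = []
        for f in order:
            rng = (range(f.start, f.end) if strand == "+"
                   else range(f.end - 1, f.start - 1, -1))
            positions.extend((f.contig, p) for p in rng)
        for idx in range(len(cds)):
            cpos = idx - phase
            if cpos < 0:
                fold = None
            else:
                codon_start = idx - (cpos % 3)
                codon = cds[codon_start:codon_start + 3]
                fold = (codon_degeneracy(codon, cpos % 3)
                        if len(codon) == 3 else None)
            contig, gpos = positions[idx]
            val = -1 if fold is None else fold
            prev = deg[contig][gpos]
            if prev == -2:
                deg[contig][gpos] = val
            elif prev != val:
                deg[contig][gpos] = -1

    for contig, d in deg.items():
        arr = classes[contig]
        touched = d != -2
        arr[touched & (d == 0)] = SiteClass.zero_fold
        arr[touched & (d == 4)] = SiteClass.four_fold
        arr[touched & ((d == 2) | (d == 3) | (d == -1))] = \
            SiteClass.other_coding_excluded

    cns = {c: np.zeros(len(s), dtype=np.int8)
           for c, s in bundle.sequences.items()}
    for iv in bundle.cns_intervals:
        try:
            cat = CnsCategory[iv.category]
        except KeyError as exc:
            raise ValueError(f"unknown CNS category {iv.category!r}") from exc
        cns[iv.contig][iv.start:iv.end] = cat
    return ClassMap(classes, cns)
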