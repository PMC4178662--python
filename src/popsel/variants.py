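"""Genotype tables: the all-sites VCF-style input and its flat-TSV dialect.

The pipeline consumes GATK-style all-sites genotype data: per site a QUAL
score, the fraction of spanning-deletion reads ('Dels'), and per individual
a genotype, read depth and phred-scaled genotype likelihoods.  Because
all-sites VCF dialects vary, the same data is accepted as a flat TSV with
identical columns; both parse to identical SiteRecord streams.

Internally sites are held columnar (:class:`VariantTable`) for vectorized
filtering; :class:`SiteRecord` is the per-site streaming view.  Positions
are 0-based internally, 1-based in both file dialects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["SiteRecord", "VariantTable", "load_variant_table",
           "read_variant_table", "write_variant_table"]

GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING = 0, 1, 2, -1
_BASES = "ACGTN"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SiteRecord:
    """One genomic position with quality annotations and per-individual
    genotype data; missing per-individual values are -1, never defaulted."""

    contig: str
    pos: int                     # 0-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    dels: float
    gt: np.ndarray               # int8 per sample
    dp: np.ndarray               # int16 per sample
    pl_best: np.ndarray          # int16 per sample
    pl_second: np.ndarray        # int16 per sample

    @property
    def is_polymorphic(self) -> bool:
        return bool(np.any(self.gt == GT_HET)
                    or np.any(self.gt == GT_HOM_ALT))

    @property
    def n_segregating_bases(self) -> int:
        present = {self.ref, *self.alts}
        return len(present)


class VariantTable:
    """Columnar all-sites genotype data for one or more contigs."""

    def __init__(self, samples: list[str], contigs: dict[str, dict]):
        self.samples = list(samples)
        self._data = contigs  # contig -> dict of arrays

    @property
    def contigs(self) -> list[str]:
        return list(self._data)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def arrays(self, contig: str) -> dict:
        return self._data[contig]

    def n_sites(self, contig: str | None = None) -> int:
        if contig is not None:
            return self._data[contig]["pos"].size
        return sum(d["pos"].size for d in self._data.values())

    @classmethod
    def allocate(cls, samples: list[str],
                 contig_sites: dict[str, np.ndarray]) -> "VariantTable":
        data = {}
        for contig, pos in contig_sites.items():
            L = pos.size
            S = len(samples)
            data[contig] = {
                "pos": pos.astype(np.int64),
                "ref": np.zeros(L, dtype=np.uint8),
                "alt": np.full(L, 255, dtype=np.uint8),
                "n_alts": np.zeros(L, dtype=np.uint8),
                "qual": np.zeros(L, dtype=np.float32),
                "dels": np.zeros(L, dtype=np.float32),
                "gt": np.zeros((L, S), dtype=np.int8),
                "dp": np.full((L, S), -1, dtype=np.int16),
                "pl_best": np.full((L, S), -1, dtype=np.int16),
                "pl_second": np.full((L, S), -1, dtype=np.int16),
            }
        return cls(samples, data)

    # -- derived per-site vectors -------------------------------------
    def alt_counts(self, contig: str) -> np.ndarray:
        """Alternate-allele copy count summed over samples (missing GT
        contributes 0)."""
        gt = self._data[contig]["gt"]
        return np.where(gt > 0, gt, 0).sum(axis=1)

    def polymorphic_mask(self, contig: str) -> np.ndarray:
        gt = self._data[contig]["gt"]
        return np.any(gt > 0, axis=1)

    def iter_records(self, contig: str | None = None
                     ) -> Iterator[SiteRecord]:
        for c in ([contig] if contig else self.contigs):
            d = self._data[c]
            for i in range(d["pos"].size):
                alt = d["alt"][i]
                alts = () if d["n_alts"][i] == 0 else (_BASES[alt],)
                if d["n_alts"][i] > 1:
                    alts = alts + ("X",) * (int(d["n_alts"][i]) - 1)
                yield SiteRecord(c, int(d["pos"][i]), _BASES[d["ref"][i]],
                                 alts, float(d["qual"][i]),
                                 float(d["dels"][i]), d["gt"][i],
                                 d["dp"][i], d["pl_best"][i],
                                 d["pl_second"][i])


# ---------------------------------------------------------------------------
# flat-TSV dialect
# ---------------------------------------------------------------------------

def write_variant_table(table: VariantTable, path) -> None:
    """Write the flat-TSV dialect (1-based positions)."""
    frames = []
    for contig in table.contigs:
        d = table.arrays(contig)
        cols = {
            "contig": contig,
            "pos": d["pos"] + 1,
            "ref": [_BASES[b] for b in d["ref"]],
            "alt": [("." if n == 0 else _BASES[a] + ("" if n == 1 else ",X"))
                    for a, n in zip(d["alt"], d["n_alts"])],
            "qual": np.round(d["qual"].astype(float), 2),
            "dels": np.round(d["dels"].astype(float), 3),
        }
        for j, s in enumerate(table.samples):
            cols[f"{s}_gt"] = d["gt"][:, j]
            cols[f"{s}_dp"] = d["dp"][:, j]
            cols[f"{s}_plb"] = d["pl_best"][:, j]
            cols[f"{s}_pls"] = d["pl_second"][:, j]
        frames.append(pd.DataFrame(cols))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def _check_monotone(pos: np.ndarray, contig: str, path) -> None:
    if pos.size > 1 and np.any(np.diff(pos) <= 0):
        raise ValueError(f"{path}: non-monotone positions on {contig}")


def read_variant_table(path, sample_ids: list[str] | None = None
                       ) -> VariantTable:
    """Read either dialect (by extension: .vcf vs anything else = TSV) into
    a columnar VariantTable."""
    path = str(path)
    if path.endswith(".vcf"):
        return _read_vcf(path, sample_ids)
    return _read_tsv(path, sample_ids)


def _read_tsv(path, sample_ids) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    in_file = [c[:-3] for c in df.columns if c.endswith("_gt")]
    samples = sample_ids if sample_ids is not None else in_file
    for s in samples:
        if s not in in_file:
            raise ValueError(f"{path}: sample {s!r} absent from header")
    data = {}
    for contig, sub in df.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64) - 1
        _check_monotone(pos, str(contig), path)
        L = pos.size
        alts = sub["alt"].astype(str).to_numpy(dtype="U8")
        n_alts = np.where(alts == ".", 0,
                          np.char.count(alts, ",") + 1).astype(np.uint8)
        alt_code = np.array([_BASE_CODE.get(a.split(",")[0], 255)
                             if a != "." else 255 for a in alts],
                            dtype=np.uint8)
        d = {
            "pos": pos,
            "ref": np.array([_BASE_CODE.get(b, 4)
                             for b in sub["ref"].astype(str)],
                            dtype=np.uint8),
            "alt": alt_code,
            "n_alts": n_alts,
            "qual": sub["qual"].to_numpy(dtype=np.float32),
            "dels": sub["dels"].to_numpy(dtype=np.float32),
            "gt": np.stack([sub[f"{s}_gt"].to_numpy(dtype=np.int8)
                            for s in samples], axis=1),
            "dp": np.stack([sub[f"{s}_dp"].to_numpy(dtype=np.int16)
                            for s in samples], axis=1),
            "pl_best": np.stack([sub[f"{s}_plb"].to_numpy(dtype=np.int16)
                                 for s in samples], axis=1),
            "pl_second": np.stack([sub[f"{s}_pls"].to_numpy(dtype=np.int16)
                                   for s in samples], axis=1),
        }
        data[str(contig)] = d
    return VariantTable(list(samples), data)


# ---------------------------------------------------------------------------
# all-sites VCF dialect
# ---------------------------------------------------------------------------

def write_vcf(table: VariantTable, path) -> None:
    """Write an all-sites VCF carrying QUAL, INFO/Dels and GT:DP:PL."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=Dels,Number=1,Type=Float,'
                 'Description="Fraction of reads containing spanning '
                 'deletions">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description='
                 '"Read depth">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
                 '"Phred-scaled genotype likelihoods">\n')
        for contig in table.contigs:
            L = int(table.arrays(contig)["pos"].max()) + 1
            fh.write(f"##contig=<ID={contig},length={L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        gt_str = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1",
                  GT_MISSING: "./."}
        for contig in table.contigs:
            d = table.arrays(contig)
            for i in range(d["pos"].size):
                n_alts = int(d["n_alts"][i])
                alt = ("." if n_alts == 0 else _BASES[d["alt"][i]]
                       + (",N" if n_alts > 1 else ""))
                fields = []
                for j in range(len(table.samples)):
                    dp = d["dp"][i, j]
                    dp_s = "." if dp < 0 else str(int(dp))
                    plb, pls = d["pl_best"][i, j], d["pl_second"][i, j]
                    if plb < 0 or n_alts == 0:
                        pl_s = "."
                    else:
                        pl_s = _pl_triple(int(d["gt"][i, j]), int(plb),
                                          int(pls))
                    fields.append(f"{gt_str[int(d['gt'][i, j])]}:{dp_s}:"
                                  f"{pl_s}")
                fh.write(f"{contig}\t{int(d['pos'][i]) + 1}\t.\t"
                         f"{_BASES[d['ref'][i]]}\t{alt}\t"
                         f"{d['qual'][i]:.2f}\t.\tDels={d['dels'][i]:.3f}\t"
                         f"GT:DP:PL\t" + "\t".join(fields) + "\n")


def _pl_triple(gt: int, best: int, second: int) -> str:
    """Reconstruct a 3-entry PL vector placing `best` at the called
    genotype and `second` at the runner-up (third entry inflated)."""
    third = max(second + 60, 120)
    vals = [third, third, third]
    if gt in (GT_HOM_REF, GT_HET, GT_HOM_ALT):
        vals[gt] = best
        runner = GT_HET if gt != GT_HET else GT_HOM_REF
        vals[runner] = second
    return ",".join(str(v) for v in vals)


def _read_vcf(path, sample_ids) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    in_file = list(vcf.samples)
    samples = sample_ids if sample_ids is not None else in_file
    idx = []
    for s in samples:
        if s not in in_file:
            raise ValueError(f"{path}: sample {s!r} absent from header")
        idx.append(in_file.index(s))
    idx = np.array(idx)

    per_contig: dict[str, list] = {}
    for v in vcf:
        per_contig.setdefault(v.CHROM, []).append(v_tuple(v, idx))
    data = {}
    for contig, rows in per_contig.items():
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        _check_monotone(pos, contig, path)
        L = len(rows)
        d = {
            "pos": pos,
            "ref": np.array([r[1] for r in rows], dtype=np.uint8),
            "alt": np.array([r[2] for r in rows], dtype=np.uint8),
            "n_alts": np.array([r[3] for r in rows], dtype=np.uint8),
            "qual": np.array([r[4] for r in rows], dtype=np.float32),
            "dels": np.array([r[5] for r in rows], dtype=np.float32),
            "gt": np.stack([r[6] for r in rows]),
            "dp": np.stack([r[7] for r in rows]),
            "pl_best": np.stack([r[8] for r in rows]),
            "pl_second": np.stack([r[9] for r in rows]),
        }
        data[contig] = d
    return VariantTable(list(samples), data)


def v_tuple(v, idx: np.ndarray):
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gtt = np.asarray(v.gt_types)[idx]
    gt = np.full(idx.size, GT_MISSING, dtype=np.int8)
    gt[gtt == 0] = GT_HOM_REF
    gt[gtt == 1] = GT_HET
    gt[gtt == 3] = GT_HOM_ALT
    dp_raw = v.format("DP")
    dp = (np.full(idx.size, -1, dtype=np.int16) if dp_raw is None
          else dp_raw.reshape(-1)[idx].astype(np.int16))
    dp[dp < 0] = -1
    plb = np.full(idx.size, -1, dtype=np.int16)
    pls = np.full(idx.size, -1, dtype=np.int16)
    pl_raw = v.format("PL")
    if pl_raw is not None:
        if pl_raw.shape[1] < 2:   # e.g. "." at invariant sites
            pl_raw = np.concatenate(
                [pl_raw, np.full((pl_raw.shape[0], 2 - pl_raw.shape[1]),
                                 -1, dtype=pl_raw.dtype)], axis=1)
        pl = pl_raw[idx].astype(np.int32)
        pl = np.where(pl < 0, np.iinfo(np.int32).max, pl)  # missing entries
        pl_sorted = np.sort(pl, axis=1)
        valid = pl_sorted[:, 0] < np.iinfo(np.int32).max
        plb[valid] = np.clip(pl_sorted[valid, 0], 0, 32000)
        has2 = valid & (pl_sorted[:, 1] < np.iinfo(np.int32).max)
        pls[has2] = np.clip(pl_sorted[has2, 1], 0, 32000)
    alts = v.ALT or []
    alt_code = _BASE_CODE.get(alts[0], 4) if alts else 255
    return (v.POS - 1, _BASE_CODE.get(v.REF, 4), alt_code, len(alts),
            v.QUAL if v.QUAL is not None else 0.0,
            float(v.INFO.get("Dels", 0.0)), gt, dp, plb, pls)


def load_variant_table(path, sample_ids: list[str] | None = None
                       ) -> Iterator[SiteRecord]:
    """Stream SiteRecords from either dialect, in coordinate order."""
    yield from read_variant_table(path, sample_ids).iter_records()
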