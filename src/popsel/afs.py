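"""Allele-frequency spectra.

An :class:`AFS` holds, for one site class, the number of sites at each
derived-allele multiplicity ``0..n`` in a sample of ``n`` chromosomes.
``counts[0]`` is the monomorphic-ancestral class, ``counts[n]`` sites fixed
for the derived allele; both are part of ``sites_assessed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AFS", "write_afs_tsv", "read_afs_tsv"]


@dataclass
class AFS:
    site_class: str
    n_chrom: int
    counts: np.ndarray  # length n_chrom + 1, float (bootstrap re-weighting) or int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_chrom + 1,):
            raise ValueError(
                f"AFS for n={self.n_chrom} needs {self.n_chrom + 1} count "
                f"classes, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative AFS counts")

    @property
    def sites_assessed(self) -> float:
        return float(self.counts.sum())

    @property
    def segregating(self) -> float:
        return float(self.counts[1:-1].sum())

    @property
    def polymorphic(self) -> np.ndarray:
        """Counts for multiplicities 1..n-1."""
        return self.counts[1:-1]

    def folded(self) -> np.ndarray:
        """Minor-allele-count spectrum, classes 1..n//2."""
        n = self.n_chrom
        out = np.zeros(n // 2 + 1)
        for i in range(1, n // 2 + 1):
            j = n - i
            out[i] = self.counts[i] + (self.counts[j] if j != i else 0.0)
        return out[1:]

    def __add__(self, other: "AFS") -> "AFS":
        if other.n_chrom != self.n_chrom:
            raise ValueError("cannot add AFS with different n_chrom")
        return AFS(self.site_class, self.n_chrom, self.counts + other.counts)


def write_afs_tsv(path, spectra: list[AFS]) -> None:
    rows = []
    for a in spectra:
        row = {"site_class": a.site_class, "n_chrom": a.n_chrom,
               "sites_assessed": a.sites_assessed}
        for i, c in enumerate(a.counts):
            row[f"count_{i}"] = c
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_afs_tsv(path) -> list[AFS]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        n = int(row["n_chrom"])
        counts = np.array([row[f"count_{i}"] for i in range(n + 1)], dtype=float)
        out.append(AFS(str(row["site_class"]), n, counts))
    return out
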