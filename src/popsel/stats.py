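"""Diversity and neutrality statistics.

Watterson's theta, pairwise pi, Tajima's D (all from class-wise AFS), and
windowed genomic tracks of 4-fold diversity, divergence, and per-sample
heterozygous/homozygous call ratios.  Diversity statistics use folded
information only, so unpolarized sites can be included upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afs import AFS

__all__ = ["DiversitySummary", "watterson_theta", "pi_from_afs", "tajima_d",
           "diversity_summary", "windowed_tracks"]


def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: float, L: float, n: int) -> float:
    """S / (a_n * L) per site, a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L <= 0:
        raise ValueError("theta_w undefined for L = 0")
    return S / (_a1(n) * L)


def pi_from_afs(afs: AFS) -> float:
    """Mean pairwise diversity per site: sum_i i(n-i) c_i / (C(n,2) L)."""
    n = afs.n_chrom
    i = np.arange(1, n)
    L = afs.sites_assessed
    if L <= 0:
        raise ValueError("pi undefined for zero assessed sites")
    return float(np.sum(i * (n - i) * afs.counts[1:n])
                 / (n * (n - 1) / 2.0) / L)


def tajima_d(afs: AFS) -> float:
    """Tajima's 1989 D from the spectrum; raises if S = 0 (undefined,
    deliberately not reported as zero)."""
    n = afs.n_chrom
    if n < 4:
        raise ValueError("need n >= 4")
    S = afs.segregating
    if S <= 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    i = np.arange(1, n)
    pi_total = float(np.sum(i * (n - i) * afs.counts[1:n])
                     / (n * (n - 1) / 2.0))
    a1 = _a1(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


@dataclass
class DiversitySummary:
    site_class: str
    S: float
    L: float
    theta_w: float
    pi: float
    tajima_d: float | None
    n_chrom: int


def diversity_summary(afs: AFS) -> DiversitySummary:
    S = afs.segregating
    L = afs.sites_assessed
    return DiversitySummary(
        afs.site_class, S, L,
        watterson_theta(S, L, afs.n_chrom),
        pi_from_afs(afs),
        tajima_d(afs) if S > 0 else None,
        afs.n_chrom)


def windowed_tracks(table, class_map, keep_mask, window: int = 20_000,
                    divergence_mask: dict[str, np.ndarray] | None = None,
                    snp_windows: int | None = None) -> pd.DataFrame:
    """Per-window 4-fold diversity (proportion of kept 4-fold sites
    segregating), 4-fold divergence, and per-sample het/hom call ratio.

    Windows are fixed-bp spans by default, or fixed segregating-site counts
    when ``snp_windows`` is given.  Windows without 4-fold sites get NaN.
    """
    from .annotate import SiteClass

    rows = []
    for contig in table.contigs:
        d = table.arrays(contig)
        keep = keep_mask[contig]
        pos = d["pos"]
        four = class_map.classes[contig][pos] == SiteClass.four_fold
        poly = np.any(d["gt"] > 0, axis=1)
        het_counts = (d["gt"] == 1).sum(axis=1)
        hom_alt = (d["gt"] == 2).sum(axis=1)
        div = (divergence_mask[contig][pos]
               if divergence_mask is not None else np.zeros(pos.size, bool))
        contig_len = int(pos.max()) + 1 if pos.size else 0
        if snp_windows:
            snp_idx = np.flatnonzero(poly & keep)
            bounds = snp_idx[::snp_windows]
            edges = list(d["pos"][bounds]) + [contig_len]
        else:
            edges = list(range(0, contig_len, window)) + [contig_len]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi <= lo:
                continue
            in_w = (pos >= lo) & (pos < hi) & keep
            n4 = int((in_w & four).sum())
            seg4 = int((in_w & four & poly).sum())
            div4 = int((in_w & four & div).sum())
            n_het = int(het_counts[in_w & poly].sum())
            n_hom = int(hom_alt[in_w & poly].sum())
            rows.append({
                "contig": contig, "start": lo, "end": hi,
                "n_4fold": n4,
                "diversity_4fold": seg4 / n4 if n4 else np.nan,
                "divergence_4fold": div4 / n4 if n4 else np.nan,
                "het_hom_ratio": n_het / n_hom if n_hom else np.nan,
            })
    return pd.DataFrame(rows)
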