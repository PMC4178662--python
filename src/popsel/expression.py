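"""Expression-stratified selection analysis.

Genes with mean FPKM >= 1 are split into four expression quartiles; each
bin gets its own 0-fold and 4-fold spectra and divergence (the bin's own
4-fold data is the neutral reference), a DFE fit, alpha/omega_a, and the
proportion of invariant replacement sites.  Confidence intervals come from
resampling genes with replacement; bin-vs-bin differences are tested with
the bootstrap randomization p-value.  The dN/dS-expression relationship is
summarized by a rank correlation with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afs import AFS
from .dfe import (DEFAULT_BIN_EDGES, AlphaEstimate, DFEFit, SfsEngine,
                  estimate_alpha_omega, fit_demography, fit_dfe,
                  percentile_ci, randomization_pvalue)

__all__ = ["ExpressionBins", "GeneSelectionData", "BinSelection",
           "bin_genes", "per_bin_selection", "correlate_dnds_expression"]

BIN_LABELS = ("low", "mid_low", "mid_high", "high")


@dataclass
class ExpressionBins:
    assignments: pd.DataFrame      # gene_id, fpkm_mean, bin
    boundaries: list[tuple[float, float]]
    labels: tuple[str, ...]

    def genes_in(self, label: str) -> list[str]:
        df = self.assignments
        return df[df["bin"] == label]["gene_id"].tolist()

    def sizes(self) -> dict[str, int]:
        return self.assignments["bin"].value_counts().to_dict()


def bin_genes(expression: pd.DataFrame, min_fpkm: float = 1.0,
              n_bins: int = 4) -> ExpressionBins:
    """Drop genes below ``min_fpkm``, sort by expression, split into
    near-equal quantile bins (ties broken by stable sort on gene id, so
    bin sizes differ by at most 1 even for degenerate inputs)."""
    df = expression[["gene_id", "fpkm_mean"]].copy()
    df = df[df["fpkm_mean"] >= min_fpkm]
    if len(df) < n_bins:
        raise ValueError(f"only {len(df)} genes at FPKM >= {min_fpkm}; "
                         f"cannot form {n_bins} bins")
    df = df.sort_values(["fpkm_mean", "gene_id"],
                        kind="stable").reset_index(drop=True)
    labels = (BIN_LABELS if n_bins == 4
              else tuple(f"bin{i + 1}" for i in range(n_bins)))
    sizes = np.full(n_bins, len(df) // n_bins)
    sizes[:len(df) % n_bins] += 1
    bin_col = np.repeat(np.arange(n_bins), sizes)
    df["bin"] = [labels[b] for b in bin_col]
    boundaries = []
    for b in range(n_bins):
        sub = df[df["bin"] == labels[b]]["fpkm_mean"]
        boundaries.append((float(sub.min()), float(sub.max())))
    return ExpressionBins(df, boundaries, labels)


@dataclass
class GeneSelectionData:
    """Per-gene sufficient statistics for bin-level selection estimates."""
    gene_ids: list[str]
    n_chrom: int
    zero_afs: np.ndarray     # (G, n+1) downsampled 0-fold spectra
    four_afs: np.ndarray     # (G, n+1)
    zero_sites: np.ndarray   # divergence-assessed replacement sites
    zero_subs: np.ndarray
    four_sites: np.ndarray
    four_subs: np.ndarray

    def index_of(self, genes: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup],
                        dtype=np.int64)


@dataclass
class BinSelection:
    label: str
    n_genes: int
    dfe: DFEFit
    alpha: AlphaEstimate
    invariant_prop: float
    replicates: dict[str, np.ndarray] = field(default_factory=dict)
    ci: dict[str, tuple] = field(default_factory=dict)


def _rate(subs, sites):
    return float(subs) / float(sites) if sites > 0 else 0.0


def _bin_estimate(data: GeneSelectionData, idx: np.ndarray,
                  bin_edges, demography=None, starts=None):
    zero = AFS("zero_fold", data.n_chrom, data.zero_afs[idx].sum(axis=0))
    four = AFS("four_fold", data.n_chrom, data.four_afs[idx].sum(axis=0))
    dfe = fit_dfe(zero, four, demography=demography, bin_edges=bin_edges,
                  starts=starts)
    d_n = _rate(data.zero_subs[idx].sum(), data.zero_sites[idx].sum())
    d_s = _rate(data.four_subs[idx].sum(), data.four_sites[idx].sum())
    alpha = (estimate_alpha_omega(dfe, d_n, d_s) if d_s > 0
             else AlphaEstimate(np.nan, np.nan, dfe.omega_na, d_n, d_s))
    n = data.n_chrom
    tot = zero.counts.sum()
    inv = float((zero.counts[0] + zero.counts[n]) / tot) if tot else np.nan
    return dfe, alpha, inv


def per_bin_selection(bins: ExpressionBins, data: GeneSelectionData,
                      reps: int = 1000,
                      rng: np.random.Generator | None = None,
                      bin_edges=DEFAULT_BIN_EDGES, demography=None
                      ) -> tuple[dict[str, BinSelection], dict[str, float]]:
    """Selection estimates per expression bin with gene bootstrap.

    Each bin's own 4-fold data is its neutral reference; a genome-wide
    demography fit may be supplied to share the nuisance across bins.
    Returns (per-bin results, pairwise randomization p-values between the
    extreme bins for the effectively-neutral DFE mass, alpha and omega_a).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    results: dict[str, BinSelection] = {}
    for label in bins.labels:
        idx = data.index_of(bins.genes_in(label))
        if idx.size == 0:
            raise ValueError(f"bin {label} has no genes with site data")
        if data.zero_sites[idx].sum() == 0 and \
                data.zero_afs[idx].sum() == 0:
            raise ValueError(f"bin {label} has no assessed 0-fold sites")
        dfe, alpha, inv = _bin_estimate(data, idx, bin_edges,
                                        demography=demography)
        res = BinSelection(label, idx.size, dfe, alpha, inv)
        warm = [(dfe.shape, dfe.mean_s)]
        reps_acc = {"neutral_mass": [], "alpha": [], "omega_a": []}
        for _ in range(reps):
            ridx = idx[rng.integers(0, idx.size, size=idx.size)]
            try:
                d, a, _ = _bin_estimate(data, ridx, bin_edges,
                                        demography=dfe.demography,
                                        starts=warm)
            except ValueError:
                continue
            reps_acc["neutral_mass"].append(d.bin_masses[0])
            reps_acc["alpha"].append(a.alpha)
            reps_acc["omega_a"].append(a.omega_a)
        res.replicates = {k: np.asarray(v) for k, v in reps_acc.items()}
        if reps:
            res.ci = {k: percentile_ci(v) for k, v in res.replicates.items()
                      if v.size}
        results[label] = res
    pvals: dict[str, float] = {}
    lo, hi = bins.labels[0], bins.labels[-1]
    if reps and results[lo].replicates["alpha"].size and \
            results[hi].replicates["alpha"].size:
        m = min(results[lo].replicates["alpha"].size,
                results[hi].replicates["alpha"].size)
        for k in ("neutral_mass", "alpha", "omega_a"):
            pvals[k] = randomization_pvalue(
                results[lo].replicates[k][:m], results[hi].replicates[k][:m])
    return results, pvals


def correlate_dnds_expression(gene_dnds: pd.DataFrame,
                              expression: pd.DataFrame,
                              n_perm: int = 10_000,
                              rng: np.random.Generator | None = None,
                              min_fpkm: float = 1.0) -> dict:
    """Rank (Spearman) correlation between per-gene dN/dS and expression,
    with a permutation p-value; Pearson on log FPKM reported alongside."""
    rng = rng if rng is not None else np.random.default_rng(0)
    df = gene_dnds.merge(expression, on="gene_id")
    df = df[(df["fpkm_mean"] >= min_fpkm) & np.isfinite(df["dN_dS"])]
    if len(df) < 10:
        raise ValueError("need at least 10 genes with dN/dS and expression")
    x = df["dN_dS"].to_numpy()
    y = df["fpkm_mean"].to_numpy()
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rx * ry))
    perms = np.empty(n_perm)
    for k in range(n_perm):
        perms[k] = np.mean(rx * rng.permutation(ry))
    p = float((np.sum(np.abs(perms) >= abs(rho)) + 1) / (n_perm + 1))
    pearson_log = float(np.corrcoef(x, np.log(y))[0, 1])
    return {"spearman_rho": rho, "permutation_p": p,
            "pearson_log_fpkm": pearson_log, "n_genes": int(len(df))}
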