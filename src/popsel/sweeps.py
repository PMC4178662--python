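"""Recurrent selective-sweep signature test.

Profiles 4-fold-degenerate diversity (proportion of sites segregating),
divergence (proportion diverged on the focal lineage), and their ratio in
non-overlapping windows extending 40 kb either side of a set of anchor
substitutions (or anchor intervals, for CNS-edge profiles).  Windows pool
4-fold sites across all anchors at the same offset.  The comparison set is
bootstrapped by substitution; after dropping the top and bottom ``trim``
replicates per offset the remaining order statistics bound the 95% CI, and
the one-tailed p-value at each offset is (i+1)/(n+2) with i the number of
replicates at or below the observed focal value — lower diversity (or
diversity/divergence) around the focal substitutions than around the
comparison set is the sweep signal.  Dividing diversity by divergence
controls for locally elevated mutation rates, which inflate both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import ClassMap, CnsCategory, SiteClass

__all__ = ["Anchor", "SweepProfile", "SweepContrast", "sweep_site_data",
           "profile_windows", "bootstrap_profile", "run_contrasts"]


@dataclass(frozen=True)
class Anchor:
    """A focal feature: a substitution (1 bp) or a CNS interval.  Sites
    inside [start, end) are excluded from the anchor's own pools; offsets
    are measured from the nearest interval edge."""
    contig: str
    start: int
    end: int


@dataclass
class SweepProfile:
    label: str
    window: int
    span: int
    offsets: np.ndarray          # left bin edges, -span .. span-window
    n_sites: np.ndarray
    segregating: np.ndarray
    diverged: np.ndarray
    n_anchors: int = 0

    @property
    def diversity(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_sites > 0,
                            self.segregating / self.n_sites, np.nan)

    @property
    def divergence(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_sites > 0,
                            self.diverged / self.n_sites, np.nan)

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.diverged > 0,
                            self.segregating / self.diverged, np.nan)

    def statistic(self, name: str) -> np.ndarray:
        return {"diversity": self.diversity, "divergence": self.divergence,
                "ratio": self.ratio}[name]


def sweep_site_data(table, class_map: ClassMap,
                    keep_mask: dict[str, np.ndarray],
                    div_call=None) -> dict[str, tuple]:
    """Per contig: sorted kept 4-fold site positions with segregating and
    diverged flags (the same polymorphism definition as the windowed
    diversity tracks: proportion of sites segregating)."""
    out = {}
    for contig in table.contigs:
        d = table.arrays(contig)
        pos = d["pos"]
        four = class_map.classes[contig][pos] == SiteClass.four_fold
        ok = four & keep_mask[contig]
        p4 = pos[ok]
        seg = np.any(d["gt"] > 0, axis=1)[ok]
        if div_call is not None:
            div = (div_call.substitution[contig][p4]
                   & div_call.assessed[contig][p4])
        else:
            div = np.zeros(p4.size, dtype=bool)
        out[contig] = (p4, seg, div)
    return out


def _anchor_matrix(anchors: list[Anchor], site_data: dict, window: int,
                   span: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-anchor, per-offset counts: (sites, segregating, diverged);
    shape (n_anchors, n_offsets)."""
    n_off = 2 * span // window
    A = len(anchors)
    n_sites = np.zeros((A, n_off), dtype=np.int64)
    n_seg = np.zeros((A, n_off), dtype=np.int64)
    n_div = np.zeros((A, n_off), dtype=np.int64)
    for k, a in enumerate(anchors):
        if a.contig not in site_data:
            continue
        p4, seg, div = site_data[a.contig]
        lo = np.searchsorted(p4, a.start - span)
        hi = np.searchsorted(p4, a.end + span)
        s = p4[lo:hi]
        inside = (s >= a.start) & (s < a.end)
        left = s < a.start
        dist = np.where(left, s - a.start, s - a.end + 1)
        # ragged contig ends simply contribute no sites at missing offsets
        binidx = (dist + span) // window
        use = ~inside & (binidx >= 0) & (binidx < n_off)
        b = binidx[use].astype(np.int64)
        np.add.at(n_sites[k], b, 1)
        np.add.at(n_seg[k], b, seg[lo:hi][use])
        np.add.at(n_div[k], b, div[lo:hi][use])
    return n_sites, n_seg, n_div


def profile_windows(anchors: list[Anchor], site_data: dict,
                    window: int = 1000, span: int = 40_000,
                    label: str = "") -> SweepProfile:
    """Pooled profile around an anchor set."""
    if not anchors:
        raise ValueError("empty anchor set")
    if span % window != 0:
        raise ValueError("span must be a multiple of the window size")
    ns, sg, dv = _anchor_matrix(anchors, site_data, window, span)
    offsets = np.arange(-span, span, window)
    return SweepProfile(label, window, span, offsets, ns.sum(axis=0),
                        sg.sum(axis=0), dv.sum(axis=0), len(anchors))


@dataclass
class SweepContrast:
    focal: SweepProfile
    comparison: SweepProfile
    statistic: str
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    p: np.ndarray                  # one-tailed per offset
    reps: int
    trim: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset_bp": self.focal.offsets,
            "window": self.focal.window,
            "focal": self.focal.statistic(self.statistic),
            "comparison": self.comparison.statistic(self.statistic),
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "p": self.p,
            "n_sites_focal": self.focal.n_sites,
        })


def bootstrap_profile(focal: SweepProfile,
                      comparison_anchors: list[Anchor], site_data: dict,
                      statistic: str = "ratio", reps: int = 1000,
                      trim: int = 25,
                      rng: np.random.Generator | None = None,
                      min_anchors: int = 50) -> SweepContrast:
    """Bootstrap the comparison set by substitution and test the focal
    profile against it, offset by offset."""
    if len(comparison_anchors) < min_anchors:
        raise ValueError(f"comparison set has {len(comparison_anchors)} "
                         f"anchors; need >= {min_anchors}")
    if reps < 2 * trim + 2:
        raise ValueError("reps must exceed 2*trim + 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    window, span = focal.window, focal.span
    ns, sg, dv = _anchor_matrix(comparison_anchors, site_data, window, span)
    A = ns.shape[0]
    comparison = SweepProfile(
        "comparison", window, span, focal.offsets, ns.sum(axis=0),
        sg.sum(axis=0), dv.sum(axis=0), A)
    draws = rng.multinomial(A, np.full(A, 1.0 / A), size=reps)  # (reps, A)
    r_sites = draws @ ns
    r_seg = draws @ sg
    r_div = draws @ dv
    with np.errstate(invalid="ignore", divide="ignore"):
        if statistic == "diversity":
            r_stat = np.where(r_sites > 0, r_seg / r_sites, np.nan)
        elif statistic == "divergence":
            r_stat = np.where(r_sites > 0, r_div / r_sites, np.nan)
        elif statistic == "ratio":
            r_stat = np.where(r_div > 0, r_seg / r_div, np.nan)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    obs = focal.statistic(statistic)
    n_off = obs.size
    ci_lo = np.full(n_off, np.nan)
    ci_hi = np.full(n_off, np.nan)
    p = np.full(n_off, np.nan)
    for j in range(n_off):
        col = r_stat[:, j]
        col = col[np.isfinite(col)]
        if col.size < 2 * trim + 2 or not np.isfinite(obs[j]):
            continue   # undefined cell, excluded from the p computation
        srt = np.sort(col)
        ci_lo[j] = srt[trim]
        ci_hi[j] = srt[col.size - 1 - trim]
        i = int(np.sum(srt <= obs[j]))
        p[j] = (i + 1) / (col.size + 2)
    return SweepContrast(focal, comparison, statistic, ci_lo, ci_hi, p,
                         reps, trim)


# ---------------------------------------------------------------------------
# standard contrasts
# ---------------------------------------------------------------------------

def _sub_anchors(registry: pd.DataFrame, mask) -> list[Anchor]:
    sub = registry[mask]
    return [Anchor(c, int(p), int(p) + 1)
            for c, p in zip(sub["contig"], sub["pos"])]


def run_contrasts(fixed_registry: pd.DataFrame, bundle, class_map: ClassMap,
                  site_data: dict, window: int = 1000, span: int = 40_000,
                  reps: int = 1000, trim: int = 25,
                  statistics: tuple = ("diversity", "divergence", "ratio"),
                  rng: np.random.Generator | None = None,
                  min_anchors: int = 50) -> dict[str, dict[str, SweepContrast]]:
    """The three anchored contrasts of the sweep analysis:

    - replacement (0-fold) vs silent (4-fold) fixed substitutions;
    - fixed substitutions in CNSs vs in non-conserved noncoding sequence;
    - CNS intervals containing >= 1 fixed substitution vs CNSs without
      (offsets measured from the CNS edge).

    ``fixed_registry`` must carry contig, pos, site_class, cns_category for
    substitutions already restricted to population-fixed sites.  A contrast
    whose either side is too small is skipped (logged as absent from the
    result).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    reg = fixed_registry
    out: dict[str, dict[str, SweepContrast]] = {}

    noncoding = reg["site_class"].isin([
        SiteClass.intergenic.name, SiteClass.intron_internal.name,
        SiteClass.intron_junction.name, SiteClass.utr5.name,
        SiteClass.utr3.name])
    in_cns = reg["cns_category"] != CnsCategory.none.name
    pairs = {
        "replacement_vs_silent": (
            _sub_anchors(reg, reg["site_class"] == SiteClass.zero_fold.name),
            _sub_anchors(reg, reg["site_class"] == SiteClass.four_fold.name)),
        "cns_vs_nonconserved": (
            _sub_anchors(reg, noncoding & in_cns),
            _sub_anchors(reg, noncoding & ~in_cns)),
    }
    # CNS-interval anchored contrast
    sub_pos = {c: set(reg[reg["contig"] == c]["pos"]) for c in
               reg["contig"].unique()}
    with_sub, without_sub = [], []
    for iv in bundle.cns_intervals:
        hits = sub_pos.get(iv.contig, set())
        a = Anchor(iv.contig, iv.start, iv.end)
        if any(iv.start <= p < iv.end for p in hits):
            with_sub.append(a)
        else:
            without_sub.append(a)
    pairs["cns_with_sub_vs_without"] = (with_sub, without_sub)

    for name, (focal_a, comp_a) in pairs.items():
        if len(focal_a) == 0 or len(comp_a) < min_anchors:
            continue
        focal = profile_windows(focal_a, site_data, window, span,
                                label=name + ":focal")
        out[name] = {}
        for stat in statistics:
            out[name][stat] = bootstrap_profile(
                focal, comp_a, site_data, statistic=stat, reps=reps,
                trim=trim, rng=rng, min_anchors=min_anchors)
    return out
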