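"""Genotype quality filters, region masking, IBD detection, and
construction of downsampled allele-frequency spectra.

Filter battery (site level):

1. site QUAL below 90 -> excluded
2. spanning-deletion read fraction ('Dels') not 0 -> excluded
3. any individual's depth < 20 or > 60 -> excluded
4. (polymorphic sites) any individual's best genotype PL != 0 -> excluded
5. (polymorphic sites) any individual's second-best PL < 40 -> excluded

plus: sites with more than 2 segregating bases are excluded, and whole 20 kb
windows are dropped when fewer than 30% of their sites pass everything else
(this removes repetitive, unreliably-genotyped regions wholesale).

Identity-by-descent is flagged per sample in 200 kb windows by the
inbreeding coefficient F_IS = 1 - H_obs/H_exp; windows with F_IS > 0.5 are
IBD.  When spectra are built, a sample contributes only one chromosome
inside its IBD tracts, and every site is downsampled to a fixed 23
chromosomes (hypergeometric) so no IBD region is sampled twice from the
same individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .afs import AFS
from .annotate import ClassMap, CnsCategory, SiteClass
from .variants import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, \
    SiteRecord, VariantTable

logger = logging.getLogger(__name__)

__all__ = ["FilterConfig", "IBDTract", "passes_invariant_filters",
           "passes_polymorphic_filters", "site_pass_masks",
           "region_pass_filter", "detect_ibd", "ibd_site_matrix",
           "build_afs", "genotype_discordance"]


@dataclass(frozen=True)
class FilterConfig:
    qual_min: float = 90.0
    dp_min: int = 20
    dp_max: int = 60
    pl_best_max: int = 0
    pl_second_min: int = 40
    region_window: int = 20_000
    region_min_frac: float = 0.30
    ibd_window: int = 200_000
    fis_threshold: float = 0.5
    ibd_min_sites: int = 50
    target_n: int = 23
    downsample: str = "stochastic"   # or "expected"


@dataclass(frozen=True)
class IBDTract:
    sample: str
    contig: str
    start: int
    end: int
    fis: float


# ---------------------------------------------------------------------------
# per-record predicates (the auditable, order-independent form)
# ---------------------------------------------------------------------------

def passes_invariant_filters(record: SiteRecord,
                             cfg: FilterConfig = FilterConfig()) -> bool:
    """Filters (1)-(3); missing depth fails conservatively."""
    if record.qual < cfg.qual_min:
        return False
    if record.dels != 0:
        return False
    dp = record.dp
    if np.any(dp < 0):
        return False
    return bool(np.all((dp >= cfg.dp_min) & (dp <= cfg.dp_max)))


def passes_polymorphic_filters(record: SiteRecord,
                               cfg: FilterConfig = FilterConfig()) -> bool:
    """Filters (4)-(5), applied on top of (1)-(3) at polymorphic sites."""
    plb, pls = record.pl_best, record.pl_second
    if np.any(plb < 0) or np.any(pls < 0):
        return False
    return bool(np.all(plb <= cfg.pl_best_max)
                and np.all(pls >= cfg.pl_second_min))


# ---------------------------------------------------------------------------
# vectorized masks
# ---------------------------------------------------------------------------

def site_pass_masks(table: VariantTable, contig: str,
                    cfg: FilterConfig = FilterConfig()
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(pass_mask, polymorphic_mask) for one contig.

    ``pass_mask`` is True where the site survives filters (1)-(3), plus
    (4)-(5) if polymorphic, plus the biallelic requirement.  The filters are
    pure per-site predicates, so application order cannot change the result.
    """
    d = table.arrays(contig)
    inv_ok = ((d["qual"] >= cfg.qual_min)
              & (d["dels"] == 0)
              & np.all((d["dp"] >= cfg.dp_min) & (d["dp"] <= cfg.dp_max),
                       axis=1))
    poly = np.any(d["gt"] > 0, axis=1) | (d["n_alts"] > 0)
    pl_ok = (np.all((d["pl_best"] >= 0)
                    & (d["pl_best"] <= cfg.pl_best_max), axis=1)
             & np.all(d["pl_second"] >= cfg.pl_second_min, axis=1))
    biallelic = d["n_alts"] <= 1
    no_missing_gt = np.all(d["gt"] != GT_MISSING, axis=1)
    pass_mask = inv_ok & biallelic & (~poly | (pl_ok & no_missing_gt))
    n = pass_mask.size
    logger.info("%s: %d/%d sites pass filters (1)-(5) "
                "(%d polymorphic candidates, %d multi-allelic excluded)",
                contig, int(pass_mask.sum()), n, int(poly.sum()),
                int((~biallelic).sum()))
    return pass_mask, poly & pass_mask


def region_pass_filter(pass_mask: np.ndarray, contig_length: int,
                       window: int = 20_000,
                       min_frac: float = 0.30) -> np.ndarray:
    """Mask of sites in *excluded* windows.

    Non-overlapping windows tile the contig; a window is excluded iff the
    fraction of its sites passing all other filters is strictly below
    ``min_frac``.  A contig shorter than one window is a single window.
    """
    if contig_length < window:
        window = contig_length
    n_win = max(1, int(np.ceil(contig_length / window)))
    excluded = np.zeros(pass_mask.size, dtype=bool)
    pos = np.arange(pass_mask.size)
    win_id = np.minimum(pos // window, n_win - 1)
    for w in range(n_win):
        lo = w * window
        hi = contig_length if w == n_win - 1 else (w + 1) * window
        span = hi - lo
        in_w = win_id == w
        frac = pass_mask[in_w].sum() / span
        if frac < min_frac:
            excluded[in_w] = True
    return excluded


# ---------------------------------------------------------------------------
# identity by descent
# ---------------------------------------------------------------------------

def detect_ibd(table: VariantTable, poly_pass: dict[str, np.ndarray],
               cfg: FilterConfig = FilterConfig()) -> list[IBDTract]:
    """Flag per-sample 200 kb windows with F_IS above threshold.

    F_IS is computed per sample per window as 1 - H_obs/H_exp, with H_exp
    the mean over usable polymorphic sites of 2p(1-p) from the full-sample
    alternate-allele frequency.  Adjacent flagged windows are merged into
    tracts.  Windows with fewer than ``ibd_min_sites`` usable sites are
    skipped (F_IS undefined).
    """
    tracts: list[IBDTract] = []
    for contig in table.contigs:
        d = table.arrays(contig)
        mask = poly_pass[contig]
        if not mask.any():
            continue
        pos = d["pos"][mask]
        gt = d["gt"][mask]
        called = gt != GT_MISSING
        alt_copies = np.where(gt > 0, gt, 0)
        n_chrom = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = alt_copies.sum(axis=1) / n_chrom
        h_exp_site = 2 * p * (1 - p)
        contig_len = int(d["pos"].max()) + 1
        n_win = max(1, int(np.ceil(contig_len / cfg.ibd_window)))
        win_id = np.minimum(pos // cfg.ibd_window, n_win - 1)
        for j, sample in enumerate(table.samples):
            flagged: list[tuple[int, float]] = []
            for w in range(n_win):
                in_w = win_id == w
                use = in_w & called[:, j] & (n_chrom > 0)
                n_use = int(use.sum())
                if n_use < cfg.ibd_min_sites:
                    logger.info("%s %s window %d: only %d usable sites, "
                                "F_IS undefined, skipped", contig, sample,
                                w, n_use)
                    continue
                h_exp = h_exp_site[use].mean()
                if h_exp <= 0:
                    continue
                h_obs = float((gt[use, j] == GT_HET).mean())
                fis = 1.0 - h_obs / h_exp
                if fis > cfg.fis_threshold:
                    flagged.append((w, fis))
            # merge adjacent flagged windows
            run: list[tuple[int, float]] = []
            for w, fis in flagged + [(-10, 0.0)]:
                if run and w != run[-1][0] + 1:
                    start = run[0][0] * cfg.ibd_window
                    end = min((run[-1][0] + 1) * cfg.ibd_window, contig_len)
                    tracts.append(IBDTract(sample, contig, start, end,
                                           max(f for _, f in run)))
                    run = []
                if w >= 0:
                    run.append((w, fis))
    return tracts


def ibd_site_matrix(table: VariantTable, contig: str,
                    tracts: list[IBDTract]) -> np.ndarray:
    """(L, S) boolean: site lies in that sample's IBD tract."""
    d = table.arrays(contig)
    out = np.zeros((d["pos"].size, len(table.samples)), dtype=bool)
    s_index = {s: j for j, s in enumerate(table.samples)}
    pos = d["pos"]
    for t in tracts:
        if t.contig != contig:
            continue
        j = s_index[t.sample]
        out[(pos >= t.start) & (pos < t.end), j] = True
    return out


def write_ibd_bed(tracts: list[IBDTract], path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tracts, key=lambda t: (t.sample, t.contig, t.start)):
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.sample}\t"
                     f"{t.fis:.4f}\n")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def downsampled_counts(table: VariantTable, contig: str,
                       ancestral: dict[str, np.ndarray],
                       tracts: list[IBDTract],
                       keep_mask: dict[str, np.ndarray],
                       cfg: FilterConfig = FilterConfig(),
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Downsampled derived-allele counts for one contig.

    Returns (positions, derived_count) for usable sites: kept by the
    filters, polarizable (outgroups agree and the ancestral base matches
    one of the site's alleles), and with a contributed pool of at least
    ``target_n`` chromosomes.  Each sample contributes 2 chromosomes, or 1
    inside its own IBD tract (the contributed allele drawn once from its
    genotype); the pool is downsampled to ``target_n`` by a hypergeometric
    draw ("stochastic") or rounded expectation ("expected").
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_t = cfg.target_n
    d = table.arrays(contig)
    keep = keep_mask[contig]
    if not keep.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    pos = d["pos"][keep]
    anc = ancestral[contig][pos]
    polarizable = anc != 4
    ref = d["ref"][keep]
    alt = d["alt"][keep]
    gt = d["gt"][keep]
    anc_is_ref = anc == ref
    anc_is_alt = (alt != 255) & (anc == alt)
    ok = polarizable & (anc_is_ref | anc_is_alt | (alt == 255))
    called = gt != GT_MISSING
    alt_copies = np.where(gt > 0, gt, 0)
    # derived copies per sample: alt copies if the ancestral base is the
    # reference, else the flipped count; invariant diverged sites come out
    # fixed-derived
    der_copies = np.where(anc_is_ref[:, None], alt_copies,
                          np.where(called, 2 - alt_copies, 0))
    ibd = ibd_site_matrix(table, contig, tracts)[keep]
    contrib = np.where(called, np.where(ibd, 1, 2), 0)
    # IBD single-chromosome contribution: hom -> its allele, het -> coin
    half = np.where(der_copies == 2, 1,
                    np.where(der_copies == 1,
                             rng.integers(0, 2, size=der_copies.shape), 0))
    der_contrib = np.where(ibd, half, der_copies)
    pool = contrib.sum(axis=1)
    der = der_contrib.sum(axis=1)
    usable = ok & (pool >= n_t)
    n_dropped = int((~usable & polarizable).sum())
    if n_dropped:
        logger.info("%s: %d polarizable sites dropped (pool < %d or "
                    "allele/outgroup mismatch)", contig, n_dropped, n_t)
    pool_u = pool[usable]
    der_u = der[usable]
    if cfg.downsample == "stochastic":
        sub = rng.hypergeometric(der_u, pool_u - der_u, n_t)
    else:
        sub = np.rint(der_u * n_t / pool_u).astype(np.int64)
    return pos[usable], sub


def grouped_afs(table: VariantTable, ancestral: dict[str, np.ndarray],
                tracts: list[IBDTract], keep_mask: dict[str, np.ndarray],
                groups: dict[str, np.ndarray], n_groups: int,
                cfg: FilterConfig = FilterConfig(),
                rng: np.random.Generator | None = None) -> np.ndarray:
    """AFS counts accumulated per group id.

    ``groups`` maps contig -> per-position int array (-1 = no group).
    Returns an (n_groups, target_n + 1) count matrix.
    """
    n_t = cfg.target_n
    out = np.zeros((n_groups, n_t + 1))
    for contig in table.contigs:
        pos, sub = downsampled_counts(table, contig, ancestral, tracts,
                                      keep_mask, cfg, rng)
        if pos.size == 0:
            continue
        g = groups[contig][pos]
        sel = g >= 0
        np.add.at(out, (g[sel], sub[sel]), 1)
    return out


def build_afs(table: VariantTable, class_map: ClassMap,
              ancestral: dict[str, np.ndarray],
              tracts: list[IBDTract],
              keep_mask: dict[str, np.ndarray],
              cfg: FilterConfig = FilterConfig(),
              rng: np.random.Generator | None = None,
              by_cns: bool = False) -> dict[str, AFS]:
    """Unfolded AFS per site class (or per CNS category with ``by_cns``)
    at a fixed ``target_n`` chromosomes; see :func:`downsampled_counts`
    for the IBD-aware downsampling contract."""
    if by_cns:
        groups = {c: np.where(class_map.cns[c] == CnsCategory.none,
                              -1, class_map.cns[c]).astype(np.int32)
                  for c in table.contigs}
        enum, skip = CnsCategory, {CnsCategory.none}
    else:
        groups = {c: class_map.classes[c].astype(np.int32)
                  for c in table.contigs}
        enum, skip = SiteClass, set()
    counts = grouped_afs(table, ancestral, tracts, keep_mask, groups,
                         len(enum), cfg, rng)
    out = {}
    for e in enum:
        if e in skip or counts[e].sum() == 0:
            continue
        out[e.name] = AFS(e.name, cfg.target_n, counts[e])
    return out



# ---------------------------------------------------------------------------
# genotype concordance (validation utility)
# ---------------------------------------------------------------------------

def genotype_discordance(calls_a, calls_b,
                         exclude_multiallelic: bool = True
                         ) -> tuple[int, int, float]:
    """Compare two per-site diploid base-call sets.

    Each call is an unordered pair of bases (e.g. ``("A", "G")``); ``None``
    marks no-calls, which are not compared.  Sites where the two call sets
    jointly show more than two distinct bases are excluded when
    ``exclude_multiallelic`` (such sites cannot be represented by a
    biallelic genotyping protocol).  Returns (mismatches, compared, rate).
    """
    mism = 0
    compared = 0
    for a, b in zip(calls_a, calls_b, strict=True):
        if a is None or b is None:
            continue
        if exclude_multiallelic and len(set(a) | set(b)) > 2:
            compared += 1          # assessed sequence, discordant protocol
            mism += 1
            continue
        compared += 1
        if frozenset(a) != frozenset(b):
            mism += 1
    rate = mism / compared if compared else float("nan")
    return mism, compared, rate
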