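"""Genotype filters, region masking, IBD detection and downsampling."""

import numpy as np
import pytest

from popsel.filters import (FilterConfig, IBDTract, detect_ibd,
                            downsampled_counts, genotype_discordance,
                            passes_invariant_filters,
                            passes_polymorphic_filters, region_pass_filter,
                            site_pass_masks)
from popsel.variants import SiteRecord, VariantTable


def _record(qual=100.0, dels=0.0, dp=34, plb=0, pls=50, n=3):
    return SiteRecord("c", 0, "A", ("G",), qual, dels,
                      np.ones(n, dtype=np.int8),
                      np.full(n, dp, dtype=np.int16),
                      np.full(n, plb, dtype=np.int16),
                      np.full(n, pls, dtype=np.int16))


@pytest.mark.parametrize("kwargs,expect", [
    (dict(qual=89.0), False),           # quality just below the cutoff
    (dict(qual=90.0), True),            # boundary passes
    (dict(dels=0.01), False),           # any spanning-deletion reads
    (dict(dp=19), False),
    (dict(dp=61), False),
    (dict(dp=20), True),
    (dict(dp=60), True),
])
def test_invariant_filters(kwargs, expect):
    assert passes_invariant_filters(_record(**kwargs)) is expect


def test_missing_depth_fails_conservatively():
    r = _record()
    r.dp[1] = -1
    assert passes_invariant_filters(r) is False


@pytest.mark.parametrize("plb,pls,expect", [
    (0, 40, True),      # boundary: second-best exactly 40 passes
    (0, 39, False),
    (3, 50, False),     # best genotype not certain
])
def test_polymorphic_filters(plb, pls, expect):
    assert passes_polymorphic_filters(_record(plb=plb, pls=pls)) is expect


def test_filter_predicates_order_independent(dataset, run_config):
    """The vectorized mask equals the conjunction of per-record predicates
    on a sample of sites (pure predicates: order cannot matter)."""
    contig = dataset.table.contigs[0]
    d = dataset.table.arrays(contig)
    pass_mask, _ = site_pass_masks(dataset.table, contig,
                                   run_config.filters)
    idx = np.random.default_rng(0).integers(
        0, dataset.table.n_sites(contig), 300)
    for i in idx:
        rec = SiteRecord(contig, int(d["pos"][i]), "A",
                         ("G",) if d["n_alts"][i] else (),
                         float(d["qual"][i]), float(d["dels"][i]),
                         d["gt"][i], d["dp"][i], d["pl_best"][i],
                         d["pl_second"][i])
        expect = passes_invariant_filters(rec, run_config.filters)
        if expect and (np.any(rec.gt > 0) or rec.alts):
            expect = (passes_polymorphic_filters(rec, run_config.filters)
                      and d["n_alts"][i] <= 1
                      and not np.any(rec.gt == -1))
        assert bool(pass_mask[i]) == expect, i


def _designed_table():
    """40 sites with one violation of each filter; the rest pass."""
    t = VariantTable.allocate([f"s{i}" for i in range(3)],
                              {"chr1": np.arange(40, dtype=np.int64)})
    d = t.arrays("chr1")
    d["qual"][:] = 150.0
    d["dp"][:] = 34
    poly = [5, 15, 25, 30, 31, 32, 35]
    for i in poly:
        d["gt"][i] = [0, 1, 0]
        d["alt"][i] = 1
        d["n_alts"][i] = 1
        d["pl_best"][i] = 0
        d["pl_second"][i] = 55
    d["qual"][10] = 89.0          # filter 1
    d["dels"][11] = 0.2           # filter 2
    d["dp"][12, 0] = 19           # filter 3 low
    d["dp"][13, 2] = 61           # filter 3 high
    d["pl_best"][30, 1] = 3       # filter 4
    d["pl_second"][31, 0] = 39    # filter 5
    d["n_alts"][32] = 2           # three segregating bases
    failing = {10, 11, 12, 13, 30, 31, 32}
    return t, failing


def test_designed_fixture_keeps_exact_survivors(run_config):
    table, failing = _designed_table()
    pass_mask, _ = site_pass_masks(table, "chr1", run_config.filters)
    assert set(np.flatnonzero(~pass_mask)) == failing


def test_region_filter_30_percent_boundary():
    """5,999/20,000 passing drops the window; 6,000 keeps it."""
    flags = np.zeros(40_000, dtype=bool)
    flags[:5_999] = True
    flags[20_000:26_000] = True
    excluded = region_pass_filter(flags, 40_000, window=20_000,
                                  min_frac=0.30)
    assert excluded[:20_000].all()
    assert not excluded[20_000:].any()


def test_region_filter_all_pass_empty_mask():
    flags = np.ones(50_000, dtype=bool)
    assert not region_pass_filter(flags, 50_000).any()


def test_region_filter_short_contig_single_window():
    flags = np.zeros(5_000, dtype=bool)   # 0% passing
    assert region_pass_filter(flags, 5_000).all()


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------

def _hwe_table(n_sites=4000, n_samples=8, span=400_000, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(span, size=n_sites, replace=False))
    t = VariantTable.allocate([f"s{i:02d}" for i in range(n_samples)],
                              {"chr1": pos.astype(np.int64)})
    d = t.arrays("chr1")
    d["qual"][:] = 150.0
    d["dp"][:] = 34
    p = rng.uniform(0.05, 0.95, size=n_sites)
    d["gt"][:] = rng.binomial(2, p[:, None], size=(n_sites, n_samples))
    d["alt"][:] = 1
    d["n_alts"][:] = 1
    d["pl_best"][:] = 0
    d["pl_second"][:] = 55
    return t


def test_hwe_population_yields_no_tracts():
    t = _hwe_table()
    poly = {"chr1": np.ones(t.n_sites("chr1"), dtype=bool)}
    assert detect_ibd(t, poly) == []


def test_fully_homozygous_sample_flagged():
    t = _hwe_table(seed=1)
    d = t.arrays("chr1")
    het = d["gt"][:, 0] == 1
    d["gt"][het, 0] = 2          # erase sample 0's heterozygosity
    poly = {"chr1": np.ones(t.n_sites("chr1"), dtype=bool)}
    tracts = detect_ibd(t, poly)
    assert {tr.sample for tr in tracts} == {"s00"}
    assert all(tr.fis > 0.5 for tr in tracts)


def test_sparse_window_skipped():
    t = _hwe_table(n_sites=60, span=400_000)  # ~30 sites per 200kb window
    poly = {"chr1": np.ones(t.n_sites("chr1"), dtype=bool)}
    assert detect_ibd(t, poly) == []


def test_synthetic_tract_recovered_within_one_window(analysis, run_config):
    """Every simulated IBD tract is found with <= 1-window boundary error."""
    win = run_config.ibd_window
    found = {(t.sample, t.contig): (t.start, t.end)
             for t in analysis.tracts}
    for truth in analysis.dataset.truth.ibd_tracts:
        key = (truth.sample, truth.contig)
        assert key in found, f"tract {key} missed"
        s, e = found[key]
        assert abs(s - truth.start) <= win
        assert abs(e - truth.end) <= win
    assert len(analysis.tracts) == len(analysis.dataset.truth.ibd_tracts)


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def _one_site_table(gts, ibd_samples=(), anc_is_ref=True):
    n = len(gts)
    t = VariantTable.allocate([f"s{i:02d}" for i in range(n)],
                              {"chr1": np.arange(1, dtype=np.int64)})
    d = t.arrays("chr1")
    d["qual"][:] = 150.0
    d["dp"][:] = 34
    d["ref"][:] = 0
    d["gt"][0] = gts
    if any(g > 0 for g in gts):
        d["alt"][0] = 1
        d["n_alts"][0] = 1
        d["pl_best"][0] = 0
        d["pl_second"][0] = 55
    anc = {"chr1": np.array([0 if anc_is_ref else 1], dtype=np.uint8)}
    tracts = [IBDTract(f"s{i:02d}", "chr1", 0, 10, 1.0)
              for i in ibd_samples]
    keep = {"chr1": np.ones(1, dtype=bool)}
    return t, anc, tracts, keep


def test_downsampling_preserves_expected_frequency():
    """26 chromosomes, derived count 5, target 23: mean 5*23/26, matching
    the hypergeometric."""
    gts = [2, 2, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]   # 5 derived copies
    t, anc, _, keep = _one_site_table(gts)
    draws = []
    rng = np.random.default_rng(0)
    for _ in range(2000):
        _, sub = downsampled_counts(t, "chr1", anc, [], keep, rng=rng)
        draws.append(sub[0])
    draws = np.asarray(draws)
    expect = 5 * 23 / 26
    from scipy.stats import hypergeom
    sd = hypergeom(26, 5, 23).std()
    assert abs(draws.mean() - expect) < 3 * sd / np.sqrt(len(draws))
    assert set(np.unique(draws)) <= set(range(2, 6))


def test_three_ibd_samples_make_downsampling_identity():
    """Pool of exactly 23 chromosomes: the draw is the identity."""
    gts = [2, 0, 0, 2, 2, 0, 0, 0, 0, 0, 0, 0, 0]
    t, anc, tracts, keep = _one_site_table(gts, ibd_samples=(1, 2, 5))
    for seed in range(20):
        _, sub = downsampled_counts(t, "chr1", anc, tracts, keep,
                                    rng=np.random.default_rng(seed))
        assert sub[0] == 6   # 3 hom-derived non-IBD samples: 2+2+2
    # monomorphic site increments class 0 only
    t2, anc2, _, keep2 = _one_site_table([0] * 13)
    _, sub2 = downsampled_counts(t2, "chr1", anc2, [], keep2)
    assert sub2[0] == 0


def test_ibd_sample_contributes_single_chromosome():
    gts = [2] + [0] * 12
    t, anc, tracts, keep = _one_site_table(gts, ibd_samples=(0,))
    for seed in range(5):
        _, sub = downsampled_counts(t, "chr1", anc, tracts, keep,
                                    rng=np.random.default_rng(seed))
        # pool = 25, derived = 1 -> downsample keeps it with p = 23/25
        assert sub[0] in (0, 1)


def test_flipped_polarity_counts_reference_as_derived():
    # invariant site whose outgroup-ancestral base differs from the
    # reference: a fixed derived difference, counted in the top class
    gts = [0] * 13
    t, anc, _, keep = _one_site_table(gts, anc_is_ref=False)
    pos, sub = downsampled_counts(t, "chr1", anc, [], keep)
    assert pos.size == 1 and sub[0] == 23
    # polymorphic site where the ancestral base matches neither allele:
    # unpolarizable, excluded
    gts2 = [1] + [0] * 12
    t2, anc2, _, keep2 = _one_site_table(gts2, anc_is_ref=False)
    t2.arrays("chr1")["alt"][0] = 3          # anc=1, ref=0, alt=3
    anc2["chr1"][0] = 1
    pos2, _ = downsampled_counts(t2, "chr1", anc2, [], keep2)
    assert pos2.size == 0


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_discordance_counts_and_excludes():
    a = [("A", "A"), ("A", "G"), ("C", "C"), None, ("T", "T")]
    b = [("A", "A"), ("A", "A"), ("C", "T"), ("G", "G"), ("T", "T")]
    mism, compared, rate = genotype_discordance(a, b)
    assert (mism, compared) == (2, 4)
    assert rate == pytest.approx(0.5)
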