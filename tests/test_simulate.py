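"""The synthetic-data generator: determinism, spectrum sampling, genotype
noise calibration, IBD and trough mechanics, expression coupling."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from popsel.afs import AFS
from popsel.annotate import SiteClass, classify_sites
from popsel.dfe import SfsEngine
from popsel.simulate import (GammaDFE, NEUTRAL, SimConfig, default_scenario,
                             inject_sweep_troughs, sample_sfs_prf,
                             simulate_dataset, simulate_expression,
                             simulate_genome, sweep_scenario)


def test_same_seed_identical_genome(two_gene_config):
    a = simulate_genome(two_gene_config, np.random.default_rng(9))
    b = simulate_genome(two_gene_config, np.random.default_rng(9))
    assert a.sequences == b.sequences
    assert a.features == b.features
    assert a.cns_intervals == b.cns_intervals


def test_same_seed_identical_dataset_files(tmp_path, two_gene_config):
    from popsel.genome import write_genome_bundle
    cfg = replace(two_gene_config, contig_length=20_000)
    for name in ("a", "b"):
        ds = simulate_dataset(cfg, seed=4)
        write_genome_bundle(ds.bundle, tmp_path / f"{name}.fa",
                            tmp_path / f"{name}.gff3")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gff3").read_bytes() == \
        (tmp_path / "b.gff3").read_bytes()


def test_zero_cns_density(two_gene_config):
    cfg = replace(two_gene_config, cns_density=0.0)
    bundle = simulate_genome(cfg, np.random.default_rng(1))
    assert bundle.cns_intervals == []


def test_short_introns_rejected():
    cfg = replace(default_scenario(), intron_len=50)
    with pytest.raises(ValueError, match="70"):
        simulate_genome(cfg, np.random.default_rng(0))


def test_incompatible_exon_layout_rejected():
    cfg = replace(default_scenario(), exon_cds_len=100, n_exons=1)
    with pytest.raises(ValueError, match="divisible by 3"):
        simulate_genome(cfg, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# PRF spectrum sampling
# ---------------------------------------------------------------------------

def test_neutral_sampled_sfs_proportional_to_1_over_i():
    rng = np.random.default_rng(0)
    n, L, theta = 4, 2_000_000, 0.01
    afs = sample_sfs_prf(theta, n, NEUTRAL, L, rng)
    for i in range(1, n):
        mean = L * theta / i
        assert abs(afs.counts[i] - mean) < 3 * np.sqrt(mean)


def test_selection_removes_segregation():
    rng = np.random.default_rng(1)
    n, L, theta = 23, 500_000, 0.01
    neu = sample_sfs_prf(theta, n, NEUTRAL, L, rng)
    sel = sample_sfs_prf(theta, n, GammaDFE(0.5, 50.0), L, rng)
    assert sel.segregating < neu.segregating


def test_empty_input_and_theta_guard():
    rng = np.random.default_rng(2)
    assert sample_sfs_prf(0.02, 23, NEUTRAL, 0, rng).counts.sum() == 0
    with pytest.raises(ValueError, match="theta too large"):
        sample_sfs_prf(5.0, 23, NEUTRAL, 100, rng)


# ---------------------------------------------------------------------------
# population table
# ---------------------------------------------------------------------------

def test_ibd_tract_has_no_heterozygotes(dataset):
    for t in dataset.truth.ibd_tracts:
        d = dataset.table.arrays(t.contig)
        j = dataset.table.samples.index(t.sample)
        in_tract = (d["pos"] >= t.start) & (d["pos"] < t.end)
        assert not np.any(d["gt"][in_tract, j] == 1)


def test_low_qual_fraction_calibrated(dataset):
    cfg = dataset.truth.config
    lows = []
    for c in dataset.table.contigs:
        q = dataset.table.arrays(c)["qual"]
        lows.append((q < 90).mean())
    frac = np.mean(lows)
    n = dataset.table.n_sites()
    sd = np.sqrt(cfg.low_qual_fraction * (1 - cfg.low_qual_fraction) / n)
    assert abs(frac - cfg.low_qual_fraction) < 4 * sd


def test_watterson_recovery_from_emitted_table(dataset):
    """Raw 4-fold segregating fraction recovers theta within 10%."""
    theta = dataset.truth.config.theta
    n = 2 * dataset.truth.config.n_individuals
    an = sum(1 / i for i in range(1, n))
    seg = tot = 0
    for c in dataset.table.contigs:
        d = dataset.table.arrays(c)
        four = dataset.class_map.classes[c] == SiteClass.four_fold
        seg += (four & np.any(d["gt"] > 0, axis=1)).sum()
        tot += four.sum()
    assert seg / tot / an == pytest.approx(theta, rel=0.10)


def test_registry_rates_match_configuration(dataset):
    reg = dataset.truth.registry
    cfg = dataset.truth.config
    counts = dataset.class_map.counts()
    four_subs = (reg["site_class"] == "four_fold").sum()
    rate = four_subs / counts["four_fold"]
    sd = np.sqrt(cfg.d_s / counts["four_fold"])
    assert abs(rate - cfg.d_s) < 3 * sd
    zero = reg[(reg["site_class"] == "zero_fold")
               & (reg["cns_category"] == "none")]
    # adaptive fraction at replacement sites: gene-level mixture around the
    # configured class alpha
    assert zero["adaptive"].mean() == pytest.approx(
        cfg.alpha["zero_fold"], abs=0.08)


def test_zero_divergence_empty_registry(two_gene_config):
    cfg = replace(two_gene_config, d_s=0.0, outgroup_disagreement=0.0)
    ds = simulate_dataset(cfg, seed=2)
    assert len(ds.truth.registry) == 0


# ---------------------------------------------------------------------------
# troughs
# ---------------------------------------------------------------------------

def _trough_inputs(seed=5):
    cfg = replace(sweep_scenario(), contig_length=120_000, n_contigs=1)
    ds = simulate_dataset(replace(cfg, trough_depth=0.0), seed=seed)
    return cfg, ds


def test_depth_zero_leaves_table_unchanged():
    cfg, ds = _trough_inputs()
    before = {c: ds.table.arrays(c)["gt"].copy() for c in ds.table.contigs}
    out = inject_sweep_troughs(ds.table, ds.truth.registry, ds.class_map,
                               ds.truth, np.random.default_rng(0))
    for c in out.contigs:
        np.testing.assert_array_equal(out.arrays(c)["gt"], before[c])


def test_invalid_depth_rejected():
    cfg, ds = _trough_inputs()
    ds.truth.config.trough_depth = 1.5
    with pytest.raises(ValueError, match="depth"):
        inject_sweep_troughs(ds.table, ds.truth.registry, ds.class_map,
                             ds.truth, np.random.default_rng(0))


def test_near_delta_trough_only_removes_adjacent_sites():
    """depth=1 with a vanishing decay length removes essentially only
    sites at distance ~0."""
    cfg, ds = _trough_inputs(seed=7)
    ds.truth.config.trough_depth = 1.0
    ds.truth.config.trough_decay = 0.5
    before = {c: ds.table.arrays(c)["gt"].copy() for c in ds.table.contigs}
    inject_sweep_troughs(ds.table, ds.truth.registry, ds.class_map,
                         ds.truth, np.random.default_rng(0))
    anchors = ds.truth.registry[ds.truth.registry["recent"]]
    for c in ds.table.contigs:
        changed = np.flatnonzero(
            np.any(ds.table.arrays(c)["gt"] != before[c], axis=1))
        a = anchors[anchors["contig"] == c]["pos"].to_numpy()
        for pos in changed:
            assert np.min(np.abs(a - pos)) <= 3


def test_trough_thinning_matches_analytic_expectation():
    """With depth 0.5 and 5 kb decay, 4-fold diversity within 1 kb of a
    trough-bearing substitution is reduced by about the mean thinning
    factor relative to the far field."""
    cfg, ds = _trough_inputs(seed=11)
    ds.truth.config.trough_depth = 0.5
    ds.truth.config.trough_decay = 5000.0
    c = ds.table.contigs[0]
    before = np.any(ds.table.arrays(c)["gt"] > 0, axis=1).copy()
    inject_sweep_troughs(ds.table, ds.truth.registry, ds.class_map,
                         ds.truth, np.random.default_rng(0))
    after = np.any(ds.table.arrays(c)["gt"] > 0, axis=1)
    anchors = ds.truth.registry[
        (ds.truth.registry["contig"] == c)
        & ds.truth.registry["recent"]]["pos"].to_numpy()
    four = ds.class_map.classes[c] == SiteClass.four_fold
    cand = np.flatnonzero(four & before)
    # analytic survival probability per site
    log_surv = np.zeros(cand.size)
    for a in anchors:
        d = np.abs(cand - a)
        p = 0.5 * np.exp(-d / 5000.0)
        log_surv += np.log1p(-np.minimum(p, 1 - 1e-12))
    surv = np.exp(log_surv)
    kept = after[cand]
    assert abs(kept.mean() - surv.mean()) < 3 * np.sqrt(
        np.sum(surv * (1 - surv))) / cand.size


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_zero_coupling_breaks_rank_correlation():
    cfg = replace(default_scenario(), expression_coupling=0.0)
    ids = [f"g{i:05d}" for i in range(2000)]
    df, mult = simulate_expression(ids, cfg, np.random.default_rng(0))
    assert np.allclose(mult, 1.0)
    # and with coupling on, multiplier tracks expression rank
    cfg2 = replace(cfg, expression_coupling=3.8)
    df2, mult2 = simulate_expression(ids, cfg2, np.random.default_rng(0))
    sel = (df2["fpkm_mean"] >= 1).to_numpy()
    from scipy.stats import spearmanr
    rho = spearmanr(mult2[sel], df2["fpkm_mean"].to_numpy()[sel]).statistic
    assert rho > 0.99


def test_degenerate_equal_fpkm_still_bins():
    from popsel.expression import bin_genes
    df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(8)],
                       "fpkm_mean": [5.0] * 8})
    bins = bin_genes(df)
    assert sorted(bins.sizes().values()) == [2, 2, 2, 2]


def test_low_expression_fraction_filtered_downstream():
    cfg = default_scenario()
    ids = [f"g{i:05d}" for i in range(3000)]
    df, _ = simulate_expression(ids, cfg, np.random.default_rng(3))
    frac = (df["fpkm_mean"] < 1.0).mean()
    # the low-expression component sits almost entirely below 1 FPKM, plus
    # the tail of the expressed component
    expect = cfg.low_expression_fraction * 0.95
    assert frac == pytest.approx(expect, abs=0.04)
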