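"""The PRF/DFE statistical core: expected spectra, fixation-rate ratio,
demography nuisance, gamma-DFE ML fit, alpha/omega, bootstrap machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from popsel.afs import AFS
from popsel.dfe import (BlockData, SfsEngine, TwoEpochDemography,
                        block_bootstrap, estimate_alpha_omega,
                        expected_sfs_selected, fit_demography, fit_dfe,
                        fixation_rate_ratio, gamma_bin_masses,
                        omega_nonadaptive, randomization_pvalue)
from popsel.dfe import DFEFit, _two_epoch_shape, _constant_sfs_shapes


def test_neutral_sfs_identity():
    """S=0 expectations are exactly proportional to 1/i (n=23)."""
    sfs, fix = expected_sfs_selected(1.0, 23, 0.0)
    i = np.arange(1, 23)
    assert np.max(np.abs(sfs * i - 1.0)) < 1e-10
    assert fix == pytest.approx(1.0)


def test_deleterious_spectrum_is_rare_skewed():
    """S=-20 inflates the singleton proportion relative to neutral."""
    neu, _ = expected_sfs_selected(1.0, 23, 0.0)
    sel, _ = expected_sfs_selected(1.0, 23, -20.0)
    assert sel[0] / sel.sum() > neu[0] / neu.sum()
    assert sel.sum() < neu.sum()       # selection removes variants


def test_fixation_rate_ratio_values_and_continuity():
    assert fixation_rate_ratio(np.array(-4.0)) == pytest.approx(
        4 / (math.e**4 - 1))
    assert fixation_rate_ratio(np.array(4.0)) == pytest.approx(
        4 / (1 - math.exp(-4)))
    for eps in (1e-6, -1e-6):
        assert abs(fixation_rate_ratio(np.array(eps)) - 1.0) < 1e-5


def test_out_of_range_selection_rejected():
    with pytest.raises(ValueError):
        expected_sfs_selected(1.0, 23, -501.0)
    with pytest.raises(ValueError):
        expected_sfs_selected(1.0, 3, -1.0)


def test_exponential_bin_mass_closed_form():
    """beta=1 (exponential), E[S]=10: mass(|S|<1) = 1 - e^{-0.1}."""
    masses = gamma_bin_masses(1.0, 10.0)
    assert masses[0] == pytest.approx(1 - math.exp(-0.1), rel=1e-12)
    assert masses.sum() == pytest.approx(1.0)


def test_bin_edges_must_increase():
    with pytest.raises(ValueError):
        gamma_bin_masses(0.5, 10.0, edges=(0.0, 10.0, 1.0, np.inf))


def test_gamma_mixture_against_dense_integration():
    eng = SfsEngine(23)
    got = eng.gamma_sfs(0.3, 302.0)
    S = np.logspace(-8, np.log10(500.0), 4000)
    pdf = stats.gamma.pdf(S, 0.3, scale=302.0 / 0.3)
    dense = np.trapezoid(eng.sfs(-S) * pdf[:, None], S, axis=0)
    dense += (1 - stats.gamma.cdf(500.0, 0.3, scale=302.0 / 0.3)) \
        * eng.sfs([-500.0])[0]
    dense += stats.gamma.cdf(1e-8, 0.3, scale=302.0 / 0.3) \
        * eng.sfs([0.0])[0]
    assert np.max(np.abs(got / dense - 1)) < 1e-3


def test_omega_na_against_adaptive_quadrature():
    from scipy import integrate

    def quad_omega(beta, mean):
        f = lambda S: stats.gamma.pdf(S, beta, scale=mean / beta) * (
            S / np.expm1(min(S, 700.0)) if S > 1e-9 else 1.0)
        return sum(integrate.quad(f, a, b, limit=200)[0]
                   for a, b in [(0, 1e-3), (1e-3, 1), (1, 10), (10, 100),
                                (100, np.inf)])

    for beta, mean in [(0.3, 302.0), (0.4, 400.0), (1.0, 10.0),
                       (0.1, 1000.0)]:
        assert omega_nonadaptive(beta, mean) == pytest.approx(
            quad_omega(beta, mean), rel=1e-3)


def test_two_epoch_flat_limit_recovers_closed_form():
    dem = TwoEpochDemography(1.0, 0.5)
    for S in (0.0, -5.0):
        shape = _two_epoch_shape(23, S, dem)
        closed = _constant_sfs_shapes(23, [S])[0]
        assert np.max(np.abs(shape / closed - 1)) < 1e-9


def test_two_epoch_expansion_skews_toward_rare():
    """A recent expansion raises the singleton fraction."""
    dem = TwoEpochDemography(3.0, 0.2)
    shape = _two_epoch_shape(23, 0.0, dem)
    const = _constant_sfs_shapes(23, [0.0])[0]
    assert shape[0] / shape.sum() > const[0] / const.sum()


def _poisson_afs(rng, shape_vec, theta, L, n, label="x"):
    counts = np.zeros(n + 1)
    counts[1:n] = rng.poisson(L * theta * shape_vec)
    counts[0] = L - counts.sum()
    return AFS(label, n, counts)


def test_demography_recovery():
    """Size-ratio point estimates: near 1 for constant-size data; within
    25% for a 2x expansion at 1e5 neutral sites."""
    n, L, theta = 23, 100_000, 0.02
    rng = np.random.default_rng(3)
    const = _poisson_afs(rng, _constant_sfs_shapes(n, [0.0])[0], theta, L, n)
    fit = fit_demography(const)
    assert 0.6 < fit.n2_over_n1 < 1.7
    dem = TwoEpochDemography(2.0, 0.3)
    exp_afs = _poisson_afs(rng, _two_epoch_shape(n, 0.0, dem), theta, L, n)
    fit2 = fit_demography(exp_afs)
    assert fit2.n2_over_n1 == pytest.approx(2.0, rel=0.25)


def test_demography_requires_segregation():
    counts = np.zeros(24)
    counts[0] = 1000
    with pytest.raises(ValueError):
        fit_demography(AFS("x", 23, counts))


def test_fit_dfe_likelihood_not_below_start():
    """The optimizer's final composite log-likelihood is at least the value
    at its own starting lattice points."""
    from popsel.dfe import _DFE_START_LATTICE
    rng = np.random.default_rng(11)
    n, L, theta = 23, 50_000, 0.02
    eng = SfsEngine(23)
    sel = _poisson_afs(rng, eng.gamma_sfs(0.5, 50.0), theta, L, n, "sel")
    neu = _poisson_afs(rng, eng.sfs([0.0])[0], theta, L, n, "neu")
    dem = TwoEpochDemography()
    fit = fit_dfe(sel, neu, demography=dem)
    for b0, m0 in _DFE_START_LATTICE:
        start_fit = fit_dfe(sel, neu, demography=dem, starts=[(b0, m0)])
        assert fit.loglik >= start_fit.loglik - 1e-6


def test_fit_dfe_input_contracts():
    counts = np.zeros(24)
    counts[0] = 100
    neu = AFS("n", 23, counts)
    sel10 = AFS("s", 10, np.zeros(11))
    with pytest.raises(ValueError, match="n_chrom"):
        fit_dfe(sel10, neu)
    with pytest.raises(ValueError):
        fit_dfe(AFS("s", 23, np.zeros(24)), neu)


def test_alpha_omega_identities():
    dem = TwoEpochDemography()
    neutral_fit = DFEFit(0.3, 0.0, 0.02, gamma_bin_masses(0.3, 0.0),
                         (0, 1, 10, 100, np.inf), 0.0, dem, 23)
    a = estimate_alpha_omega(neutral_fit, d_n=0.1, d_s=0.1)
    assert a.omega_na == pytest.approx(1.0)
    assert a.alpha == pytest.approx(0.0, abs=1e-12)
    assert a.omega_a == pytest.approx(0.0, abs=1e-12)
    strong = DFEFit(2.0, 450.0, 0.02, gamma_bin_masses(2.0, 450.0),
                    (0, 1, 10, 100, np.inf), 0.0, dem, 23)
    b = estimate_alpha_omega(strong, d_n=0.05, d_s=0.1)
    assert b.omega_na < 0.02
    assert b.alpha == pytest.approx(1.0, abs=0.05)
    assert b.omega_a == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError):
        estimate_alpha_omega(strong, d_n=0.05, d_s=0.0)
    nan_a = estimate_alpha_omega(strong, d_n=0.0, d_s=0.1)
    assert math.isnan(nan_a.alpha)


def test_randomization_pvalue_rules():
    a = np.arange(1000, dtype=float)
    b = a - 0.5
    b[:4] = a[:4] + 0.5      # prop(b > a) = 0.004, prop(a > b) = 0.996
    assert randomization_pvalue(a, b) == pytest.approx(0.008)
    assert randomization_pvalue(a, a) == 0.0     # below resolution
    with pytest.raises(ValueError):
        randomization_pvalue(a, b[:10])
    # cap at 1
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=500), rng.normal(size=500)
    assert randomization_pvalue(x, y) <= 1.0


def _toy_blocks(rng, n_blocks=30, L_block=2000):
    n = 23
    eng = SfsEngine(n)
    theta = 0.02
    sel_shape = eng.gamma_sfs(0.4, 400.0)
    neu_shape = eng.sfs([0.0])[0]
    nc = np.zeros((n_blocks, n + 1))
    sc = np.zeros((n_blocks, n + 1))
    for b in range(n_blocks):
        sc[b, 1:n] = rng.poisson(L_block * theta * sel_shape)
        sc[b, 0] = L_block - sc[b].sum()
        nc[b, 1:n] = rng.poisson(L_block * theta * neu_shape)
        nc[b, 0] = L_block - nc[b].sum()
    d_s, alpha = 0.14, 0.4
    w_na = omega_nonadaptive(0.4, 400.0)
    d_n = d_s * w_na / (1 - alpha)
    ns = np.full(n_blocks, L_block)
    ss = np.full(n_blocks, L_block)
    nd = rng.binomial(L_block, d_s, n_blocks)
    sd = rng.binomial(L_block, d_n, n_blocks)
    return BlockData(nc, sc, ns, nd, ss, sd)


def test_block_bootstrap_contracts():
    rng = np.random.default_rng(5)
    blocks = _toy_blocks(rng)
    est = lambda *totals: float(totals[3]) / float(totals[2])
    reps = block_bootstrap(blocks, 50, est, np.random.default_rng(1))
    assert len(reps) == 50
    # determinism under a fixed seed
    reps2 = block_bootstrap(blocks, 50, est, np.random.default_rng(1))
    assert reps == reps2
    assert block_bootstrap(blocks, 0, est, rng) == []
    small = BlockData(blocks.neutral_counts[:10], blocks.selected_counts[:10],
                      blocks.neutral_sites[:10], blocks.neutral_subs[:10],
                      blocks.selected_sites[:10], blocks.selected_subs[:10])
    with pytest.raises(ValueError, match="blocks"):
        block_bootstrap(small, 10, est, rng)


def test_bootstrap_ci_width_shrinks_with_data():
    """Quadrupling the block count shrinks the bootstrap CI roughly like
    1/sqrt(block count) for a smooth statistic (d_s here)."""
    est = lambda *t: float(t[3]) / float(t[2])
    widths = []
    for n_blocks in (25, 100):
        rng = np.random.default_rng(9)
        blocks = _toy_blocks(rng, n_blocks=n_blocks)
        reps = block_bootstrap(blocks, 200, est, np.random.default_rng(2))
        lo, hi = np.quantile(reps, [0.025, 0.975])
        widths.append(hi - lo)
    ratio = widths[0] / widths[1]
    assert 1.3 < ratio < 3.2     # ideal 2.0
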