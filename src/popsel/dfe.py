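"""Distribution-of-fitness-effects inference from allele-frequency spectra.

The statistical core of the pipeline: Poisson-random-field (PRF) expected
spectra under genic selection, a two-epoch demographic nuisance model, a
maximum-likelihood gamma DFE over the scaled selection strength
``S = 4*Ne*s``, and the derived adaptive-substitution statistics ``alpha``
(proportion of fixed differences driven by positive selection) and
``omega_a`` (adaptive substitution rate relative to neutral divergence).

Model
-----
Under the PRF at constant population size, derived alleles at independent
sites segregate with density

    f(x; S) = theta * (1 - exp(-S (1 - x))) / ((1 - exp(-S)) x (1 - x))

per site, which reduces to ``theta / x`` at ``S = 0``.  Binomial sampling of
``n`` chromosomes gives the expected count in each frequency class.  A
deleterious DFE is a gamma density over ``|S|``; its expected spectrum is the
gamma mixture of the fixed-S spectra, integrated by generalized
Gauss-Laguerre quadrature.  A step change in population size (ratio
``N2/N1`` at scaled time ``t2`` before the present) is handled by evolving
the allele-frequency distribution through a discretized Wright-Fisher
transition matrix; for nearly flat demographies the constant-size closed
form is used directly.

Divergence enters through Kimura's fixation-rate ratio
``r(S) = S / (1 - exp(-S))``: the nonadaptive substitution rate at selected
sites relative to neutral is ``omega_na = E[r(-|S|)]`` under the fitted
gamma, and ``alpha = (d_n - d_s * omega_na) / d_n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .afs import AFS

__all__ = [
    "TwoEpochDemography",
    "DemographyFit",
    "DFEFit",
    "AlphaEstimate",
    "expected_sfs_selected",
    "fixation_rate_ratio",
    "omega_nonadaptive",
    "gamma_bin_masses",
    "SfsEngine",
    "fit_demography",
    "fit_dfe",
    "estimate_alpha_omega",
    "BlockData",
    "block_bootstrap",
    "bootstrap_dfe_alpha",
    "randomization_pvalue",
    "percentile_ci",
]

S_MAX = 500.0  # numerical range of the selection strength
DEFAULT_BIN_EDGES = (0.0, 1.0, 10.0, 100.0, np.inf)


# ---------------------------------------------------------------------------
# fixed-S expected spectra (constant size, closed form)
# ---------------------------------------------------------------------------

def _selected_shape(x: np.ndarray, S) -> np.ndarray:
    """PRF density f(x; S)/theta, numerically stable over |S| <= S_MAX.

    ``S`` is signed (negative = deleterious); scalar or array.  With an
    array S of shape (k,) and x of shape (m,), returns (k, m).
    """
    x = np.asarray(x, dtype=float)
    S_arr = np.atleast_1d(np.asarray(S, dtype=float))[:, None]
    xr = x[None, :]
    out = np.empty((S_arr.shape[0], x.size))
    neutral = np.abs(S_arr[:, 0]) < 1e-9
    out[neutral] = 1.0 / xr
    pos = S_arr[:, 0] > 1e-9
    if np.any(pos):
        Sp = S_arr[pos]
        out[pos] = (-np.expm1(-Sp * (1.0 - xr))
                    / (-np.expm1(-Sp) * xr * (1.0 - xr)))
    neg = S_arr[:, 0] < -1e-9
    if np.any(neg):
        # (1-e^{a(1-x)})/(1-e^{a}) = e^{-a x}(1-e^{-a(1-x)})/(1-e^{-a})
        a = -S_arr[neg]
        out[neg] = (np.exp(-a * xr) * (-np.expm1(-a * (1.0 - xr)))
                    / (-np.expm1(-a) * xr * (1.0 - xr)))
    if np.isscalar(S) or np.asarray(S).ndim == 0:
        return out[0]
    return out


class _Quadrature:
    """Gauss-Legendre nodes on (0,1) with the binomial sampling kernel.

    ``kernel[i-1, j] = C(n,i) x_j^i (1-x_j)^(n-i) w_j`` so that expected
    class counts for theta=1 are ``kernel @ shape(x)``.
    """

    _cache: dict[tuple[int, int], "_Quadrature"] = {}

    def __init__(self, n: int, n_points: int = 512):
        nodes, weights = np.polynomial.legendre.leggauss(n_points)
        x = 0.5 * (nodes + 1.0)
        w = 0.5 * weights
        i = np.arange(1, n)
        logbin = (special.gammaln(n + 1) - special.gammaln(i + 1)
                  - special.gammaln(n - i + 1))
        logk = (logbin[:, None] + i[:, None] * np.log(x)[None, :]
                + (n - i)[:, None] * np.log1p(-x)[None, :])
        self.x = x
        self.kernel = np.exp(logk) * w[None, :]
        self.n = n

    @classmethod
    def get(cls, n: int, n_points: int = 512) -> "_Quadrature":
        key = (n, n_points)
        if key not in cls._cache:
            cls._cache[key] = cls(n, n_points)
        return cls._cache[key]


def _constant_sfs_shapes(n: int, S_values: np.ndarray,
                         n_points: int = 512) -> np.ndarray:
    """Expected counts (theta=1) per class 1..n-1 for each S. Shape (k, n-1)."""
    q = _Quadrature.get(n, n_points)
    S_values = np.clip(np.atleast_1d(np.asarray(S_values, dtype=float)),
                       -S_MAX, S_MAX)
    h = _selected_shape(q.x, S_values)
    return h @ q.kernel.T


def fixation_rate_ratio(S) -> np.ndarray | float:
    """Kimura's relative fixation rate r(S) = S/(1-e^{-S}), with r(0)=1."""
    S = np.asarray(S, dtype=float)
    out = np.ones_like(S)
    nz = np.abs(S) > 1e-9
    with np.errstate(over="ignore"):
        out[nz] = S[nz] / -np.expm1(-np.clip(S[nz], -700, 700))
    # deep-deleterious underflow: r -> 0
    out[S < -700] = 0.0
    return out if out.ndim else float(out)


def expected_sfs_selected(theta: float, n: int, S: float,
                          demography: "TwoEpochDemography | None" = None,
                          n_points: int = 512) -> tuple[np.ndarray, float]:
    """Expected polymorphic counts (classes 1..n-1) per site, and the
    relative fixation rate ``r(S)`` governing the divergence side.

    ``theta`` is the per-site scaled mutation rate 4*Ne*mu.
    """
    if n < 4:
        raise ValueError("need n >= 4 chromosomes")
    if abs(S) > S_MAX:
        raise ValueError(f"|S| = {abs(S)} outside numerical range {S_MAX}")
    if demography is not None and not demography.is_flat():
        engine = SfsEngine(n, demography=demography, n_points=n_points)
        sfs = theta * engine.sfs([S])[0]
    else:
        sfs = theta * _constant_sfs_shapes(n, [S], n_points)[0]
    if not np.all(np.isfinite(sfs)):
        raise FloatingPointError(f"non-finite expected SFS at S={S}")
    return sfs, float(fixation_rate_ratio(np.array(S)))


# ---------------------------------------------------------------------------
# two-epoch Wright-Fisher matrix machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoEpochDemography:
    """Step change from ancestral size N1 to current size N2 = ratio * N1,
    ``t2`` scaled generations (units of 2*N2) before the present."""

    size_ratio: float = 1.0
    t2: float = 0.0

    def __post_init__(self):
        if self.size_ratio <= 0:
            raise ValueError("size_ratio must be positive")
        if self.t2 < 0:
            raise ValueError("t2 must be >= 0")

    def is_flat(self, tol: float = 0.05) -> bool:
        return abs(math.log(self.size_ratio)) < tol or self.t2 == 0.0


def _wf_transition(two_n: int, S: float) -> np.ndarray:
    """Row-stochastic WF transition matrix over derived counts 0..2N with
    genic selection of scaled strength S (= 4*N*s at this matrix size)."""
    s = S / (2.0 * two_n)
    j = np.arange(two_n + 1)
    p = j / two_n
    p_sel = p * (1.0 + s) / (1.0 + p * s)
    p_sel = np.clip(p_sel, 0.0, 1.0)
    k = np.arange(two_n + 1)
    logbin = (special.gammaln(two_n + 1) - special.gammaln(k + 1)
              - special.gammaln(two_n - k + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p_sel[:, None] > 0, np.log(p_sel)[:, None], -np.inf)
        logq = np.where(p_sel[:, None] < 1, np.log1p(-p_sel)[:, None], -np.inf)
        logm = logbin[None, :] + k[None, :] * logp + (two_n - k)[None, :] * logq
        logm = np.where(np.isnan(logm), -np.inf, logm)
    T = np.exp(logm)
    T[0] = 0.0
    T[0, 0] = 1.0
    T[-1] = 0.0
    T[-1, -1] = 1.0
    return T


_equi_cache: dict[tuple[int, float], np.ndarray] = {}


def _equilibrium_sojourn(two_n: int, S: float, influx: float) -> np.ndarray:
    """Equilibrium expected number of sites at each transient count 1..2N-1,
    given ``influx`` new mutations per generation entering at count 1."""
    key = (two_n, round(S, 10))
    if key not in _equi_cache:
        if len(_equi_cache) > 512:
            _equi_cache.clear()
        T = _wf_transition(two_n, S)
        Tt = T[1:-1, 1:-1]
        e1 = np.zeros(two_n - 1)
        e1[0] = 1.0
        _equi_cache[key] = np.linalg.solve(np.eye(two_n - 1) - Tt.T, e1)
    return influx * _equi_cache[key]


def _sample_from_density(n: int, two_n: int, nu: np.ndarray) -> np.ndarray:
    """Binomially sample the population density ``nu`` (counts 1..2N-1) down
    to expected sample-class counts 1..n-1."""
    p = np.arange(1, two_n) / two_n
    i = np.arange(1, n)
    logbin = (special.gammaln(n + 1) - special.gammaln(i + 1)
              - special.gammaln(n - i + 1))
    logk = (logbin[:, None] + i[:, None] * np.log(p)[None, :]
            + (n - i)[:, None] * np.log1p(-p)[None, :])
    return np.exp(logk) @ nu


_eig_cache: dict[tuple[int, float], tuple] = {}
_proj_cache: dict[tuple[int, int], np.ndarray] = {}


def _transient_eig(two_n: int, S: float):
    """Eigendecomposition of the transposed transient WF transition block,
    cached; lets the t2-generation evolution run in O(states^2)."""
    key = (two_n, round(S, 10))
    if key not in _eig_cache:
        if len(_eig_cache) > 256:
            _eig_cache.clear()
        Tt = _wf_transition(two_n, S)[1:-1, 1:-1].T
        lam, V = np.linalg.eig(Tt)
        _eig_cache[key] = (lam, V, np.linalg.inv(V))
    return _eig_cache[key]


def _projection(two_n1: int, two_n2: int) -> np.ndarray:
    """Binomial frequency-preserving projection from epoch-1 transient
    states onto epoch-2 transient states."""
    key = (two_n1, two_n2)
    if key not in _proj_cache:
        if len(_proj_cache) > 64:
            _proj_cache.clear()
        p1 = np.arange(1, two_n1) / two_n1
        k = np.arange(0, two_n2 + 1)
        logbin = (special.gammaln(two_n2 + 1) - special.gammaln(k + 1)
                  - special.gammaln(two_n2 - k + 1))
        logk = (logbin[None, :] + k[None, :] * np.log(p1)[:, None]
                + (two_n2 - k)[None, :] * np.log1p(-p1)[:, None])
        _proj_cache[key] = np.exp(logk)[:, 1:-1]
    return _proj_cache[key]


def _two_epoch_shape(n: int, S: float, demography: TwoEpochDemography,
                     matrix_n: int = 100) -> np.ndarray:
    """Expected sample SFS (theta=1, classes 1..n-1) under the step change,
    corrected by the closed-form/matrix ratio at constant size so that the
    flat limit is exact."""
    N2 = matrix_n
    N1 = int(np.clip(round(N2 / demography.size_ratio), 10, 1000))
    S1 = S * N1 / N2
    # theta = 1 refers to the current epoch: influx2 = theta/2, influx1 scaled
    nu1 = _equilibrium_sojourn(2 * N1, S1, 0.5 * N1 / N2)
    nu2 = (nu1 if N1 == N2
           else _projection(2 * N1, 2 * N2).T @ nu1)
    influx = np.zeros(2 * N2 - 1)
    influx[0] = 0.5
    # nu_g = T^g nu_0 + (sum_{k<g} T^k) influx, via the eigenbasis
    g = demography.t2 * 2 * N2
    lam, V, Vinv = _transient_eig(2 * N2, S)
    y0 = Vinv @ nu2.astype(complex)
    yi = Vinv @ influx.astype(complex)
    lam_g = lam ** g
    geo = np.where(np.abs(1.0 - lam) > 1e-12,
                   (1.0 - lam_g) / (1.0 - lam), g)
    nu2 = np.real(V @ (lam_g * y0 + geo * yi))
    raw = _sample_from_density(n, 2 * N2, np.clip(nu2, 0.0, None))
    # discretization correction: exact in the flat limit
    matrix_const = _sample_from_density(
        n, 2 * N2, _equilibrium_sojourn(2 * N2, S, 0.5))
    closed = _constant_sfs_shapes(n, [S])[0]
    return raw * closed / matrix_const


# ---------------------------------------------------------------------------
# engine: cached expected-spectrum shapes over S, gamma mixtures
# ---------------------------------------------------------------------------

class SfsEngine:
    """Expected-SFS evaluator for one sample size and demography.

    For a flat demography the constant-size closed form is evaluated
    directly; otherwise two-epoch matrix expectations are tabulated on a
    log-spaced grid of deleterious strengths and interpolated, which makes
    gamma-DFE likelihood evaluations cheap.
    """

    _cache: dict[tuple, "SfsEngine"] = {}

    @classmethod
    def get(cls, n: int, demography: TwoEpochDemography | None = None,
            matrix_n: int = 100) -> "SfsEngine":
        dem = demography or TwoEpochDemography()
        key = (n, round(dem.size_ratio, 9), round(dem.t2, 9), matrix_n)
        if key not in cls._cache:
            if len(cls._cache) > 64:
                cls._cache.clear()
            cls._cache[key] = cls(n, dem, matrix_n)
        return cls._cache[key]

    def __init__(self, n: int, demography: TwoEpochDemography | None = None,
                 matrix_n: int = 100, n_points: int = 512,
                 grid_size: int = 80):
        self.n = n
        self.demography = demography or TwoEpochDemography()
        self.n_points = n_points
        self.flat = self.demography.is_flat()
        self._interp = None
        if not self.flat:
            mags = np.concatenate([[0.0], np.logspace(-3, np.log10(S_MAX),
                                                      grid_size)])
            table = np.vstack([
                _two_epoch_shape(n, -m, self.demography, matrix_n)
                for m in mags
            ])
            from scipy.interpolate import PchipInterpolator
            self._interp = PchipInterpolator(np.log1p(mags), table, axis=0,
                                             extrapolate=False)
            self._mag_max = mags[-1]

    def sfs(self, S_values: Sequence[float]) -> np.ndarray:
        """Expected counts per class 1..n-1 (theta = 1), one row per S."""
        S_values = np.atleast_1d(np.asarray(S_values, dtype=float))
        if self.flat:
            return _constant_sfs_shapes(self.n, S_values, self.n_points)
        if np.any(S_values > 1e-9):
            raise ValueError("two-epoch expectations are tabulated for "
                             "deleterious S only")
        mags = np.clip(-S_values, 0.0, self._mag_max)
        return self._interp(np.log1p(mags))

    def gamma_sfs(self, shape: float, mean: float,
                  n_quad: int = 64) -> np.ndarray:
        """Expected counts per class (theta = 1) under a gamma DFE over the
        deleterious strength |S| with the given shape and mean.

        Integrated in the quantile domain: S_k = F^{-1}(u_k) at
        Gauss-Legendre nodes u_k on (0, 1), which adapts the quadrature to
        however the gamma concentrates its mass (essential for the small
        shapes and large means typical of replacement-site DFEs).
        """
        if mean < 1e-12:
            return self.sfs([0.0])[0]
        S, w = _gamma_quantile_nodes(shape, mean, n_quad)
        return w @ self.sfs(-S)


def _unit_leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _unit_leggauss._cache:
        nodes, weights = np.polynomial.legendre.leggauss(n)
        _unit_leggauss._cache[n] = (0.5 * (nodes + 1.0), 0.5 * weights)
    return _unit_leggauss._cache[n]


_unit_leggauss._cache = {}


def _gamma_quantile_nodes(shape: float, mean: float,
                          n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Deleterious-strength nodes and probability weights whose weighted
    sums integrate against the gamma(shape, mean) density."""
    u, w = _unit_leggauss(n_quad)
    S = stats.gamma.ppf(u, shape, scale=mean / shape)
    return np.clip(S, 0.0, S_MAX), w


def omega_nonadaptive(shape: float, mean: float, n_quad: int = 64) -> float:
    """E[r(-|S|)] under the gamma DFE: the nonadaptive substitution rate at
    selected sites relative to neutral."""
    if mean < 1e-12:
        return 1.0
    S, w = _gamma_quantile_nodes(shape, mean, n_quad)
    r = np.where(S > 1e-9, S / np.expm1(np.clip(S, 1e-9, 700.0)), 1.0)
    return float(w @ r)


def gamma_bin_masses(shape: float, mean: float,
                     edges: Sequence[float] = DEFAULT_BIN_EDGES) -> np.ndarray:
    """Probability mass of |S| in each bin, from the gamma CDF (exact)."""
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if mean < 1e-12:
        masses = np.zeros(len(edges) - 1)
        masses[0] = 1.0
        return masses
    cdf = stats.gamma.cdf(edges, shape, scale=mean / shape)
    return np.diff(cdf)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class DemographyFit:
    demography: TwoEpochDemography
    theta: float  # neutral theta per site
    loglik: float
    converged: bool = True

    @property
    def n2_over_n1(self) -> float:
        return self.demography.size_ratio

    @property
    def t2(self) -> float:
        return self.demography.t2


def _poisson_loglik(obs: np.ndarray, mean: np.ndarray) -> float:
    mean = np.clip(mean, 1e-300, None)
    return float(np.sum(obs * np.log(mean) - mean))


def fit_demography(neutral_afs: AFS,
                   matrix_n: int = 100) -> DemographyFit:
    """Fit (theta, size ratio, change time) to the neutral spectrum by
    Poisson composite likelihood over the polymorphic classes."""
    n = neutral_afs.n_chrom
    obs = neutral_afs.polymorphic
    L = neutral_afs.sites_assessed
    if obs.sum() <= 0 or L <= 0:
        raise ValueError("neutral AFS has no segregating sites")

    def negll(params: np.ndarray) -> float:
        log_ratio, t2 = params
        # size ratios in [1/5, 5] and change times within ~2*2N2 generations:
        # outside this range the two-epoch nuisance starts absorbing
        # polarization noise rather than demography
        if abs(log_ratio) > math.log(5.0) or t2 > 2.0:
            return np.inf
        dem = TwoEpochDemography(math.exp(log_ratio), max(t2, 0.0))
        if dem.is_flat(tol=1e-9):
            shape = _constant_sfs_shapes(n, [0.0])[0]
        else:
            shape = _two_epoch_shape(n, 0.0, dem, matrix_n)
        # profile theta analytically: m_i = L * theta * shape_i
        theta = obs.sum() / (L * shape.sum())
        return -_poisson_loglik(obs, L * theta * shape)

    starts = [(0.0, 0.0), (math.log(2.0), 0.2), (math.log(0.5), 0.2),
              (math.log(3.0), 0.8), (math.log(1 / 3.0), 0.8)]
    best = None
    for s in starts:
        res = optimize.minimize(negll, s, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7,
                                         "maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    log_ratio, t2 = best.x
    dem = TwoEpochDemography(math.exp(log_ratio), max(t2, 0.0))
    shape = (_constant_sfs_shapes(n, [0.0])[0] if dem.is_flat(tol=1e-9)
             else _two_epoch_shape(n, 0.0, dem, matrix_n))
    theta = obs.sum() / (L * shape.sum())
    return DemographyFit(dem, float(theta), -float(best.fun),
                         converged=bool(best.success or best.fun < np.inf))


@dataclass
class DFEFit:
    shape: float            # gamma shape beta
    mean_s: float           # gamma mean E[|S|], S = 4*Ne*s
    theta_sel: float        # per-site theta at selected sites
    bin_masses: np.ndarray
    bin_edges: tuple
    loglik: float
    demography: TwoEpochDemography
    n_chrom: int

    @property
    def omega_na(self) -> float:
        return omega_nonadaptive(self.shape, self.mean_s)


_DFE_START_LATTICE = [(0.2, 3.0), (0.2, 300.0), (0.5, 30.0),
                      (1.0, 3.0), (1.0, 300.0)]


def fit_dfe(selected_afs: AFS, neutral_afs: AFS,
            demography: TwoEpochDemography | None = None,
            bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
            matrix_n: int = 100,
            starts: Sequence[tuple[float, float]] | None = None,
            share_theta: bool = True) -> DFEFit:
    """Maximum-likelihood gamma DFE for the selected class.

    The demography is fitted on the neutral spectrum (unless supplied) and
    held fixed; (shape, mean) are then fitted to the selected spectrum by
    Poisson composite likelihood, integrating the fixed-S expectations over
    the gamma by generalized Gauss-Laguerre quadrature.  Restarts from a
    deterministic lattice guard against local optima.

    By default the selected per-site theta is tied to the neutral estimate
    (``share_theta=True``): selected and neutral sites share the mutation
    rate, and the absolute polymorphism deficit at selected sites is what
    identifies the strongly selected mass, which contributes almost no
    polymorphism of its own.  With ``share_theta=False`` the selected theta
    is profiled freely and only the spectrum shape is fitted.
    """
    if selected_afs.n_chrom != neutral_afs.n_chrom:
        raise ValueError("selected and neutral AFS have different n_chrom")
    n = selected_afs.n_chrom
    if demography is None:
        demography = fit_demography(neutral_afs, matrix_n).demography
    engine = SfsEngine.get(n, demography, matrix_n)
    obs = selected_afs.polymorphic
    L = selected_afs.sites_assessed
    if L <= 0:
        raise ValueError("selected AFS has no assessed sites")
    theta_fixed = None
    if share_theta:
        neu_shape = engine.sfs([0.0])[0]
        L_neu = neutral_afs.sites_assessed
        if L_neu <= 0:
            raise ValueError("neutral AFS has no assessed sites")
        theta_fixed = neutral_afs.polymorphic.sum() / (L_neu * neu_shape.sum())

    def negll(params: np.ndarray) -> float:
        log_shape, log_mean = params
        if not (-3.0 <= log_shape <= 2.3 and -7.0 <= log_mean <= 8.6):
            return np.inf
        shape_vec = engine.gamma_sfs(math.exp(log_shape), math.exp(log_mean))
        tot = shape_vec.sum()
        if not np.isfinite(tot) or tot <= 0:
            return np.inf
        theta = theta_fixed if theta_fixed is not None else (
            max(obs.sum(), 1e-8) / (L * tot))
        return -_poisson_loglik(obs, L * theta * shape_vec)

    best = None
    for b0, m0 in (starts if starts is not None else _DFE_START_LATTICE):
        res = optimize.minimize(
            negll, (math.log(b0), math.log(m0)), method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    beta = math.exp(best.x[0])
    mean = math.exp(best.x[1])
    if theta_fixed is not None:
        theta_sel = theta_fixed
    else:
        shape_vec = engine.gamma_sfs(beta, mean)
        theta_sel = max(obs.sum(), 1e-8) / (L * shape_vec.sum())
    return DFEFit(beta, mean, float(theta_sel),
                  gamma_bin_masses(beta, mean, bin_edges), tuple(bin_edges),
                  -float(best.fun), demography, n)


@dataclass
class AlphaEstimate:
    alpha: float
    omega_a: float
    omega_na: float
    d_n: float
    d_s: float
    alpha_ci: tuple | None = None
    omega_a_ci: tuple | None = None


def estimate_alpha_omega(dfe: DFEFit, d_n: float, d_s: float) -> AlphaEstimate:
    """alpha and omega_a from the fitted DFE and per-site divergences.

    ``d_n``/``d_s`` are substitutions per selected/neutral site on the focal
    lineage.  The expected nonadaptive divergence at selected sites is
    ``d_s * omega_na``; the excess is attributed to positive selection.
    """
    if d_s <= 0:
        raise ValueError("d_s must be positive")
    w_na = dfe.omega_na
    if d_n == 0:
        return AlphaEstimate(float("nan"), float("nan"), w_na, d_n, d_s)
    alpha = (d_n - d_s * w_na) / d_n
    omega_a = alpha * d_n / d_s
    return AlphaEstimate(float(alpha), float(omega_a), float(w_na),
                         float(d_n), float(d_s))


# ---------------------------------------------------------------------------
# bootstrap and randomization
# ---------------------------------------------------------------------------

@dataclass
class BlockData:
    """Per-block sufficient statistics for the joint DFE/alpha bootstrap.

    Each row of the arrays corresponds to one genomic block (10 kb by
    default upstream): AFS counts and divergence site/substitution counts
    for the neutral and the selected class.
    """

    neutral_counts: np.ndarray    # (n_blocks, n+1)
    selected_counts: np.ndarray   # (n_blocks, n+1)
    neutral_sites: np.ndarray     # (n_blocks,) divergence-assessed sites
    neutral_subs: np.ndarray
    selected_sites: np.ndarray
    selected_subs: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.neutral_counts.shape[0]

    def totals(self, idx: np.ndarray | None = None):
        sl = slice(None) if idx is None else idx
        return (self.neutral_counts[sl].sum(axis=0),
                self.selected_counts[sl].sum(axis=0),
                self.neutral_sites[sl].sum(), self.neutral_subs[sl].sum(),
                self.selected_sites[sl].sum(), self.selected_subs[sl].sum())


def block_bootstrap(blocks: BlockData, reps: int,
                    estimator: Callable, rng: np.random.Generator,
                    min_blocks: int = 20) -> list:
    """Resample blocks with replacement and re-run ``estimator`` on the
    summed statistics.  ``estimator`` receives the 6-tuple of totals."""
    if blocks.n_blocks < min_blocks:
        raise ValueError(
            f"only {blocks.n_blocks} blocks; need >= {min_blocks} for a "
            "meaningful CI")
    out = []
    for _ in range(reps):
        idx = rng.integers(0, blocks.n_blocks, size=blocks.n_blocks)
        out.append(estimator(*blocks.totals(idx)))
    return out


def percentile_ci(values: Sequence[float],
                  level: float = 0.95) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return (float(np.quantile(v, lo)), float(np.quantile(v, 1.0 - lo)))


@dataclass
class DfeAlphaBootstrap:
    point_dfe: DFEFit
    point_alpha: AlphaEstimate
    replicates: list  # list of (DFEFit, AlphaEstimate)

    def alpha_values(self) -> np.ndarray:
        return np.array([a.alpha for _, a in self.replicates])

    def mass_values(self, bin_idx: int) -> np.ndarray:
        return np.array([d.bin_masses[bin_idx] for d, _ in self.replicates])

    def omega_a_values(self) -> np.ndarray:
        return np.array([a.omega_a for _, a in self.replicates])


def bootstrap_dfe_alpha(blocks: BlockData, n_chrom: int, reps: int,
                        rng: np.random.Generator,
                        site_class: str = "selected",
                        bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
                        demography: TwoEpochDemography | None = None,
                        matrix_n: int = 100) -> DfeAlphaBootstrap:
    """Joint block bootstrap of the DFE fit and the alpha/omega_a estimate.

    The point fit uses the full restart lattice; bootstrap replicates are
    warm-started from the point estimate (single restart), the standard
    speed/robustness trade-off for resampling loops.
    """
    nc, sc, ns, nd, ss, sd = blocks.totals()
    neutral = AFS("neutral", n_chrom, nc)
    selected = AFS(site_class, n_chrom, sc)
    point_dfe = fit_dfe(selected, neutral, demography=demography,
                        bin_edges=bin_edges, matrix_n=matrix_n)
    point_alpha = estimate_alpha_omega(point_dfe, _rate(sd, ss), _rate(nd, ns))
    warm = [(point_dfe.shape, point_dfe.mean_s)]
    dem = point_dfe.demography

    def estimator(nc, sc, ns, nd, ss, sd):
        d = fit_dfe(AFS(site_class, n_chrom, sc), AFS("neutral", n_chrom, nc),
                    demography=dem, bin_edges=bin_edges, matrix_n=matrix_n,
                    starts=warm)
        a = estimate_alpha_omega(d, _rate(sd, ss), _rate(nd, ns))
        return (d, a)

    replicates = block_bootstrap(blocks, reps, estimator, rng) if reps else []
    boot = DfeAlphaBootstrap(point_dfe, point_alpha, replicates)
    if replicates:
        point_alpha.alpha_ci = percentile_ci(boot.alpha_values())
        point_alpha.omega_a_ci = percentile_ci(boot.omega_a_values())
    return boot


def _rate(subs: float, sites: float) -> float:
    return float(subs) / float(sites) if sites > 0 else 0.0


def randomization_pvalue(replicates_a: Sequence[float],
                         replicates_b: Sequence[float]) -> float:
    """Two-tailed bootstrap randomization p-value.

    Twice the smaller one-sided proportion of replicate pairs where one set
    exceeds the other, capped at 1.  A returned 0 means "below the 2/reps
    resolution of the replicate sets".
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length")
    pa = float(np.mean(a > b))
    pb = float(np.mean(b > a))
    return min(1.0, 2.0 * min(pa, pb))
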