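"""Forward Wright-Fisher simulator used as an independent oracle.

Simulates a diploid panmictic population of ``N`` individuals with genic
(semidominant) selection: genotype fitnesses 1, 1+s, 1+2s, so the scaled
strength is ``S = 4*N*s`` and Kimura's fixation probability of a new mutant
is ``(1 - exp(-S/(2N))) / (1 - exp(-S))``.  Desk-scale by design (N <= 1000,
single locus, no linkage); everything downstream that consumes PRF
expectations can be cross-checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WFParams", "WFResult", "wf_forward_simulate",
           "fixation_probability", "equilibrium_sample_sfs"]


@dataclass
class WFParams:
    N: int = 100                  # diploid population size
    S: float = 0.0                # scaled selection 4*N*s of the derived allele
    mu: float = 2.5e-5            # per-site mutation rate (for the SFS run)
    generations: int = 0          # SFS run length; 0 -> 20*N after burn-in
    replicates: int = 200_000     # fixation-probability replicates
    sample_n: int = 23            # chromosomes sampled for the SFS

    def __post_init__(self):
        if self.N > 1000:
            raise ValueError("desk-scale oracle: N <= 1000")
        if self.mu * 4 * self.N > 0.1:
            raise ValueError("theta = 4*N*mu > 0.1 leaves the near "
                             "infinite-sites regime")


@dataclass
class WFResult:
    fixation_prob: float
    fixation_prob_se: float
    sample_sfs: np.ndarray | None   # mean counts per class 1..n-1, per site
    sample_sfs_se: np.ndarray | None
    theta: float
    equilibrated: bool


def _select_freq(p: np.ndarray, s: float) -> np.ndarray:
    return np.clip(p * (1.0 + s) / (1.0 + p * s), 0.0, 1.0)


def fixation_probability(N: int, S: float, replicates: int,
                         rng: np.random.Generator,
                         batch: int = 200_000) -> tuple[float, float]:
    """Monte-Carlo fixation probability of a single new mutant copy."""
    two_n = 2 * N
    s = S / (2.0 * two_n)
    fixed = 0
    done = 0
    while done < replicates:
        m = min(batch, replicates - done)
        count = np.ones(m, dtype=np.int64)
        active = np.arange(m)
        while active.size:
            p = _select_freq(count[active] / two_n, s)
            count[active] = rng.binomial(two_n, p)
            sub = count[active]
            active = active[(sub > 0) & (sub < two_n)]
        fixed += int(np.sum(count == two_n))
        done += m
    phat = fixed / replicates
    se = np.sqrt(max(phat * (1 - phat), 1.0 / replicates) / replicates)
    return phat, se


def equilibrium_sample_sfs(N: int, S: float, mu: float, sample_n: int,
                           generations: int, rng: np.random.Generator,
                           n_sites: int = 100_000
                           ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Time-averaged sample SFS under recurrent mutation at ``n_sites``
    independent sites (infinite-sites bookkeeping: each site at most one
    segregating mutation; fixed or lost sites reset)."""
    two_n = 2 * N
    s = S / (2.0 * two_n)
    burn = 10 * two_n
    total = burn + (generations if generations > 0 else 10 * two_n)
    equilibrated = total - burn >= 10 * N
    influx_rate = n_sites * mu * two_n  # new mutants per generation

    counts = np.zeros(0, dtype=np.int64)  # segregating-site derived counts
    i = np.arange(1, sample_n)
    from scipy import special
    logbin = (special.gammaln(sample_n + 1) - special.gammaln(i + 1)
              - special.gammaln(sample_n - i + 1))
    acc = np.zeros(sample_n - 1)
    acc2 = np.zeros(sample_n - 1)
    n_rec = 0
    thin = max(1, N // 10)  # record every ~N/10 generations
    for gen in range(total):
        if counts.size:
            p = _select_freq(counts / two_n, s)
            counts = rng.binomial(two_n, p)
            counts = counts[(counts > 0) & (counts < two_n)]
        n_new = rng.poisson(influx_rate)
        if n_new:
            counts = np.concatenate([counts, np.ones(n_new, dtype=np.int64)])
        if gen >= burn and (gen - burn) % thin == 0:
            if counts.size:
                x = counts / two_n
                probs = np.exp(logbin[:, None] + i[:, None] * np.log(x)[None]
                               + (sample_n - i)[:, None]
                               * np.log1p(-x)[None])
                e = probs.sum(axis=1)
            else:
                e = np.zeros(sample_n - 1)
            acc += e
            acc2 += e * e
            n_rec += 1
    mean = acc / max(n_rec, 1) / n_sites
    var = acc2 / max(n_rec, 1) / n_sites**2 - mean**2
    # successive records are correlated; inflate the naive SE by the thinning
    # interval relative to the ~2N-generation coalescent correlation time
    eff = max(n_rec * thin / (2.0 * two_n), 1.0)
    se = np.sqrt(np.clip(var, 0, None) / eff)
    return mean, se, equilibrated


def wf_forward_simulate(params: WFParams, rng: np.random.Generator,
                        run_sfs: bool = False) -> WFResult:
    """Replicate-averaged fixation probability and (optionally) the
    equilibrium sample SFS."""
    phat, se = fixation_probability(params.N, params.S, params.replicates,
                                    rng)
    sfs = sfs_se = None
    equilibrated = True
    if run_sfs:
        sfs, sfs_se, equilibrated = equilibrium_sample_sfs(
            params.N, params.S, params.mu, params.sample_n,
            params.generations, rng)
    return WFResult(phat, se, sfs, sfs_se, theta=4 * params.N * params.mu,
                    equilibrated=equilibrated)
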