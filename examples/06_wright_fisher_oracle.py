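"""The forward Wright-Fisher simulator as an independent oracle.

Checks Monte-Carlo fixation probabilities against Kimura's closed form and
a simulated equilibrium spectrum against the analytic PRF expectation —
the same cross-validation the test suite uses to anchor the DFE machinery.
"""

import numpy as np

from popsel.dfe import expected_sfs_selected, fixation_rate_ratio
from popsel.wright_fisher import equilibrium_sample_sfs, \
    fixation_probability

rng = np.random.default_rng(1)
N = 100
print("fixation probability of a new mutant, relative to neutral 1/(2N):")
for S in (-4.0, 0.0, 4.0):
    p, se = fixation_probability(N, S, replicates=100_000, rng=rng)
    print(f"  S={S:+.0f}: simulated {p * 2 * N:.3f} +- {se * 2 * N:.3f}, "
          f"Kimura r(S) = {float(fixation_rate_ratio(np.array(S))):.3f}")

theta = 4 * N * 2.5e-5
sfs, se, _ = equilibrium_sample_sfs(N, -10.0, 2.5e-5, sample_n=23,
                                    generations=2000, rng=rng,
                                    n_sites=30_000)
expect, _ = expected_sfs_selected(theta, 23, -10.0)
print("\nequilibrium sample SFS at S=-10 (first 5 classes, per site):")
print("  simulated:", np.round(sfs[:5], 5))
print("  analytic :", np.round(expect[:5], 5))
# Agreement within Monte-Carlo error (and O(1/N) discretization) ties the
# likelihood machinery to an independent forward-in-time implementation.
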