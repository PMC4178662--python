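"""Recurrent-sweep signature: diversity troughs around fixed substitutions.

Simulates the sweep scenario (adaptation clustered in a subset of genes,
troughs of depth 0.5 and 5 kb decay around recent adaptive fixations),
profiles 4-fold diversity/divergence in 1 kb windows out to +-40 kb around
fixed replacement substitutions, and tests the reduction at the
substitution against a bootstrap over silent substitutions.
"""

import numpy as np

from popsel import pipeline as pl
from popsel.config import RunConfig
from popsel.simulate import simulate_dataset, sweep_scenario
from popsel.sweeps import (Anchor, bootstrap_profile, profile_windows,
                           sweep_site_data)

ds = simulate_dataset(sweep_scenario(depth=0.5), seed=3)
cfg = RunConfig()
keep, _ = pl.filter_stage(ds.table, cfg)
call, fixed, fixed_df, *_ = pl.divergence_stage(
    ds.alignment, ds.table, ds.class_map, ds.bundle, keep, cfg)
sd = sweep_site_data(ds.table, ds.class_map, keep, call)


def anchors(site_class):
    sub = fixed_df[fixed_df["site_class"] == site_class]
    return [Anchor(c, int(p), int(p) + 1)
            for c, p in zip(sub["contig"], sub["pos"])]


repl, silent = anchors("zero_fold"), anchors("four_fold")
focal = profile_windows(repl, sd, window=1000, span=40_000)
contrast = bootstrap_profile(focal, silent, sd, statistic="ratio",
                             reps=1000, trim=25,
                             rng=np.random.default_rng(11))
j0 = len(focal.offsets) // 2
print(f"{len(repl)} replacement vs {len(silent)} silent substitutions")
print(f"diversity/divergence at the substitution: "
      f"{contrast.focal.ratio[j0]:.3f} (replacement) vs "
      f"{contrast.comparison.ratio[j0]:.3f} (silent), "
      f"95% CI [{contrast.ci_lo[j0]:.3f}, {contrast.ci_hi[j0]:.3f}]")
print(f"one-tailed p = {contrast.p[j0]:.4f}  "
      "(p = 1/1002 is the formula's floor)")
# A ratio below the silent bootstrap CI at offset 0, fading with distance,
# is the classic footprint of recurrent selective sweeps; dividing by
# divergence removes mutation-rate artifacts.
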