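"""Gamma-DFE and adaptive-substitution estimates at replacement sites.

Fits the two-epoch demographic nuisance on the 4-fold spectrum, the gamma
DFE on the 0-fold spectrum (shared per-site theta), and converts the
divergence excess into alpha (proportion of adaptive fixations) and
omega_a (adaptive rate relative to neutral divergence), with block
bootstrap CIs.
"""

import numpy as np

from popsel import pipeline as pl
from popsel.config import RunConfig
from popsel.dfe import bootstrap_dfe_alpha
from popsel.simulate import default_scenario, simulate_dataset

ds = simulate_dataset(default_scenario(), seed=1)
cfg = RunConfig()
rng = np.random.default_rng(7)

keep, poly = pl.filter_stage(ds.table, cfg)
tracts = pl.ibd_stage(ds.table, poly, cfg)
call, *_ = pl.divergence_stage(ds.alignment, ds.table, ds.class_map,
                               ds.bundle, keep, cfg)
blocks = pl.make_block_data(ds.table, ds.class_map, call, tracts, keep,
                            "zero_fold", cfg, rng)
boot = bootstrap_dfe_alpha(blocks, cfg.target_n, reps=100, rng=rng)

fit, a = boot.point_dfe, boot.point_alpha
print(f"gamma DFE: shape={fit.shape:.2f}, E[S]={fit.mean_s:.0f}")
print("mass per |S| bin (0-1, 1-10, 10-100, >100):",
      np.round(fit.bin_masses, 3))
print(f"alpha = {a.alpha:.3f}  (95% CI {a.alpha_ci})")
print(f"omega_a = {a.omega_a:.3f}, omega_na = {a.omega_na:.3f}")
# The generator places ~42% of replacement fixations by positive
# selection; alpha should land nearby, with most DFE mass at |S| > 10
# (strong purifying selection on the remaining sites).
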