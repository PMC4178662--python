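"""Per-class diversity after quality filtering and IBD-aware downsampling.

Runs the genotype filters (QUAL/Dels/depth/PL, the 20 kb region mask),
flags identity-by-descent, builds downsampled spectra and prints
Watterson's theta_w, pi and Tajima's D per site class.  At the default
study conditions theta_w should be ~0.022 at 4-fold sites, lower at UTRs
and lowest at replacement sites, with D near 0 (constant-size neutral
sampling).
"""

import numpy as np

from popsel import pipeline as pl
from popsel.config import RunConfig
from popsel.simulate import default_scenario, simulate_dataset
from popsel.stats import diversity_summary

ds = simulate_dataset(default_scenario(), seed=1)
cfg = RunConfig()
rng = np.random.default_rng(7)

keep, poly = pl.filter_stage(ds.table, cfg)
tracts = pl.ibd_stage(ds.table, poly, cfg)
print(f"kept {sum(int(m.sum()) for m in keep.values())} sites; "
      f"{len(tracts)} IBD tracts")

spectra = pl.diversity_stage(ds.table, ds.class_map, tracts, keep, cfg,
                             rng)
for name in ("four_fold", "intron_internal", "intergenic", "utr5", "utr3",
             "zero_fold"):
    s = diversity_summary(spectra[name])
    print(f"{name:16s} L={s.L:8.0f}  theta_w={s.theta_w:.4f}  "
          f"pi={s.pi:.4f}  D={s.tajima_d:+.3f}")
# The ranking (4-fold ~ intergenic > introns > UTRs >> 0-fold) is the
# signature of purifying selection removing variation at functional sites.
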