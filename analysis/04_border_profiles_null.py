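#!/usr/bin/env python
"""Do the strongest activations sit on areal borders, beyond smoothness?

Runs the border analyses on a finer mesh: distance-segment activation
profiles across every core-area border with the segment x task
repeated-measures interaction, the top-5% subject-overlap map, and the
areal-homogeneous null simulation (per-subject border jitter + smoothing
at 4, 12, 20 mm FWHM).  The border-proximity of top-5% survivors on the
bump-planted cohort is compared with the same quantity on the nulls: a
higher value on the real cohort is the fingerprint of genuine border
peaks rather than blur.
"""

import logging

import pandas as pd

from mdsurf import PipelineConfig, run_pipeline

logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")

cfg = PipelineConfig(
    out_dir="results/run_borders",
    seed=20260919,
    resolution=3,  # finer mesh so proximity radii resolve area interiors
    stages=("simulate", "borders", "nullsim"),
)
run_pipeline(cfg)

inter = pd.read_csv("results/run_borders/border_interactions.csv")
prox = pd.read_csv("results/run_borders/border_proximity.csv")
null = pd.read_csv("results/run_borders/null_border_proximity.csv")
print("segment x task interactions at core borders:")
print(inter.to_string(index=False))
print(f"\nborder proximity of top-5% survivors (bump-planted): "
      f"{prox['value'][0]:.3f}")
print("same quantity on areal-homogeneous smoothed nulls:")
print(null.to_string(index=False))
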