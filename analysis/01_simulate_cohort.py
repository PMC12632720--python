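#!/usr/bin/env python
"""Simulate the demonstration cohort and persist it under results/run/.

Writes phenotypes.csv, timecourses.h5 and a hashed manifest. The latent
per-subject brain-age acceleration (true_bag) is stored for later
validation but is hidden from the analysis loader.
"""

import pandas as pd

from common import RUN_DIR, demo_config
from dynbag.pipeline import run_pipeline

cfg = demo_config()
run_pipeline(cfg, RUN_DIR, stages=["simulate"], overwrite=True)

pheno = pd.read_csv(RUN_DIR / "cohort" / "phenotypes.csv")
print(f"cohort written to {RUN_DIR / 'cohort'}")
print(f"  subjects: {len(pheno)}  (patients: {(pheno.dx == 'SZ').sum()})")
print(f"  age range: {pheno.age.min():.1f}-{pheno.age.max():.1f} y, "
      f"mean {pheno.age.mean():.1f} y")
print(f"  sites: {sorted(pheno.site.unique())}")
print("  latent acceleration by group (years):")
print(pheno.groupby("dx")["true_bag"].describe()[["mean", "std"]].round(2))
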