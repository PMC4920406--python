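#!/usr/bin/env python
"""Estimate per-species daily rewards from the raw synthetic assay tables.

Reads the assay bundle written by 01_generate_meadows.py, runs the nectar
(s = 10dvC), pollen (ellipsoid grains x haemocytometer scaling / longevity)
and longevity ((2a+(b-c))/((b-c)d)) estimators, and compares the estimated
species profiles with the generator's planted truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from meadowforage import pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"
IN = ROOT / "synthetic"
OUT = ROOT / "species_profiles_estimated.csv"

log: list[str] = []
profiles = pipeline.build_profiles(IN, log)
profiles.to_csv(OUT, index=False)

truth = pd.read_csv(IN / "truth_species.csv").set_index("species")
est = profiles.set_index("species")
shared = est.index.intersection(truth.index)

for label, est_col, truth_col in (
    ("nectar ug/unit/24h", "nectar_per_unit_day_ug", "nectar_per_unit_day_ug"),
    ("pollen ul/unit/24h", "pollen_per_unit_day_ul", "pollen_per_unit_day_ul"),
    ("longevity days", "longevity_days", "longevity_days"),
):
    ratio = est.loc[shared, est_col] / truth.loc[shared, truth_col]
    print(f"{label}: estimate/truth median {ratio.median():.3f} "
          f"(IQR {ratio.quantile(0.25):.3f}-{ratio.quantile(0.75):.3f})")

n_zero = int(est["zero_flagged"].sum()) if "zero_flagged" in est else 0
print(f"{len(est)} species profiled; {n_zero} flagged all-zero nectar")
for line in log:
    print(line)
print(f"wrote {OUT}")
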