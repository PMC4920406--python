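#!/usr/bin/env python
"""Convert meadow pollen budgets into pollinator currencies.

Expresses the synthetic study's peak daily pollen production per treatment
as pollen mass, honeybee-worker equivalents and solitary-bee brood-cell
equivalents, and the trapezoid season totals as fractions of a honeybee
colony's annual pollen harvest; the reference worked example (a perennial
meadow at 0.45 ml/m2/day over 300 m2) is printed alongside.
"""

from pathlib import Path

import pandas as pd

from meadowforage import equivalents as eq

ROOT = Path(__file__).resolve().parents[1] / "results"
constants = eq.EquivalenceConstants()

# reference worked example: peak perennial production of 0.45 ml pollen/m2/day
mass = eq.pollen_volume_to_mass(0.45)
daily = eq.meadow_daily_pollen_mass(mass)
print("reference peak perennial meadow: "
      f"0.45 ml/m2/day -> {mass:.2f} g/m2/day -> {daily:.0f} g/meadow/day "
      f"-> {eq.honeybee_worker_equivalents(daily):.0f} worker equivalents/day")

estimates = pd.read_csv(ROOT / "meadow_estimates.csv")
peak = (estimates.groupby("treatment")["pollen_per_m2_day_ul"].max()
        .rename("peak_ul_m2_day").to_frame())
peak["peak_g_m2_day"] = [
    eq.pollen_volume_to_mass(v / 1000.0) for v in peak["peak_ul_m2_day"]
]
peak["g_meadow_day"] = [
    eq.meadow_daily_pollen_mass(m) for m in peak["peak_g_m2_day"]
]
peak["workers_day"] = [
    eq.honeybee_worker_equivalents(g) for g in peak["g_meadow_day"]
]
lo, hi = constants.solitary_cell_pollen_range_g
peak["cells_day_large_bee"] = [
    eq.solitary_bee_cell_equivalents(g, hi) for g in peak["g_meadow_day"]
]
peak["cells_day_small_bee"] = [
    eq.solitary_bee_cell_equivalents(g, lo) for g in peak["g_meadow_day"]
]
peak.round(3).to_csv(ROOT / "equivalents_peak.csv")
print("peak-day equivalents per treatment:")
print(peak.round(2).to_string())

season = pd.read_csv(ROOT / "season_totals.csv")
season["season_pollen_g_meadow"] = [
    eq.meadow_daily_pollen_mass(eq.pollen_volume_to_mass(v / 1000.0))
    for v in season["season_pollen_ul_m2"]
]
season["colony_fraction"] = [
    eq.colony_requirement_fraction(g) for g in season["season_pollen_g_meadow"]
]
season.to_csv(ROOT / "equivalents_season.csv", index=False)
frac = season.groupby("treatment")["colony_fraction"].median()
print("season pollen as fraction of one colony's 20 kg/yr (median):")
print(frac.round(4).to_string())
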