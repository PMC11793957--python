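"""Descriptive stage: extreme risk behaviour at the bottom of the
resource distribution, and the time-discounting specificity contrast.
"""

from pathlib import Path

import pandas as pd

from desperation import descriptives

OUT = Path("results")
proc = pd.read_csv(OUT / "panel_processed.csv")

prevalence = descriptives.extreme_prevalence_table(proc, tail_pct=5)
prevalence.to_csv(OUT / "extreme_prevalence.csv")
print("extreme risk taking by resource tail (observation level):")
cols = ["pct_avoiders", "pct_takers", "mean_count", "var_ratio_vs_full", "n"]
print(prevalence[cols].round(2).to_string())

by_count = descriptives.mean_resources_by_count(proc)
by_count.to_csv(OUT / "mean_resources_by_count.csv")
print("\nmean resources by bet count (6 and 7 pooled):")
print(by_count.round(3).to_string())

strain = descriptives.strain_group_summary(proc)
strain.to_csv(OUT / "strain_summary.csv")
print("\nrisk taking by financial-strain answer:")
print(strain.round(3).to_string())

discount = descriptives.discounting_contrast(proc, tail_pct=5)
discount.to_csv(OUT / "discounting_contrast.csv")
print("\ntime-discounting contrast (high = all immediate, low = none):")
print(discount[["pct_high", "pct_low", "var_ratio_vs_full", "n"]].round(2).to_string())

consist = descriptives.consistency_by_resources(proc)
consist.to_csv(OUT / "consistency.csv")
print("\nconsistency vs resources (point-biserial):")
print(consist.round(3).to_string())
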