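"""Preprocessing stage: derive the analysis variables.

Reads results/panel_raw.csv, computes objective (log2 income/costs) and
subjective (reverse-coded, square-rooted insecurity) resources, bet and
immediate-choice counts, and consistency flags.
"""

from pathlib import Path

import pandas as pd

from desperation.preprocess import preprocess_panel

OUT = Path("results")
raw = pd.read_csv(OUT / "panel_raw.csv")
proc = preprocess_panel(raw)
proc.to_csv(OUT / "panel_processed.csv", index=False)

neg = (proc.objective_resources < 0).mean()
incons = (~proc.consistent).mean()
corr = proc.objective_resources.corr(proc.subjective_resources)
print(f"{len(proc)} processed observations")
print(f"{100 * neg:.1f}% of months fail to cover unavoidable costs")
print(f"{100 * incons:.1f}% of gamble batteries are inconsistent")
print(f"objective-subjective resource correlation r = {corr:.2f}")
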