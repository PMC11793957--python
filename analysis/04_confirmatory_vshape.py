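"""Confirmatory stage: is risk taking a V-shape of resources?

Two complementary tests per resource measure, both as Gaussian
random-intercept models with age and gender controls, fitted by ML:
polynomial models compared by AIC and likelihood ratio against the linear
fit, and a segmented (broken-stick) model whose changepoint is profiled
over a percentile grid to the minimum deviance.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from desperation import models

OUT = Path("results")
proc = pd.read_csv(OUT / "panel_processed.csv")

summary = {}
for var in ("objective_resources", "subjective_resources"):
    short = var.split("_")[0]
    comp = models.compare_polynomials(proc, var, max_degree=5)
    comp.aic_table.to_csv(OUT / f"poly_aic_{short}.csv")
    seg = models.fit_segmented_mixed(proc, var, n_points=199)
    seg.profile.to_csv(OUT / f"deviance_profile_{short}.csv", index=False)
    seg.coef_table().to_csv(OUT / f"segmented_coefs_{short}.csv")

    print(f"\n== {var} ==")
    aics = comp.aic_table["aic"]
    print(
        f"polynomial AICs (degree 1..5): {np.round(aics.to_numpy(), 1)}; "
        f"lowest at degree {comp.selected_degree}"
    )
    if len(comp.lrt_table):
        lrt = comp.lrt_table.loc[comp.selected_degree] if comp.selected_degree > 1 else None
        if lrt is not None:
            print(f"LRT of degree {comp.selected_degree} vs linear: p = {lrt['p']:.3f}")
    pct_below = 100.0 * seg.share_below
    print(
        f"segmented: changepoint {seg.cp:.3f} ({pct_below:.1f}% of observations "
        f"below); slope below = {seg.beta1:.3f} (p = {seg.pvalues['beta1']:.3g}), "
        f"slope above = {seg.beta2:.3f} (p = {seg.pvalues['beta2']:.3g})"
    )
    summary[var] = {
        "poly_selected_degree": comp.selected_degree,
        "segmented_cp": seg.cp,
        "share_below": seg.share_below,
        "beta1": seg.beta1,
        "beta2": seg.beta2,
        "p_beta1": seg.pvalues["beta1"],
        "p_beta2": seg.pvalues["beta2"],
    }

# the V-shape p-values corrected across the two resource measures
ps = [summary[v]["p_beta1"] for v in summary] + [summary[v]["p_beta2"] for v in summary]
adj = models.holm_bonferroni(ps)
print(f"\nHolm-adjusted segment-slope p-values: {np.round(adj, 4)}")
(OUT / "vshape_summary.json").write_text(json.dumps(summary, indent=2))
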