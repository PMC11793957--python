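"""Descriptive and contrast analyses of extreme risk behaviour.

A *risk avoider* accepts no gambles at all; a *risk taker* accepts more
than four — anyone taking five or more necessarily preferred the gamble to
a sure amount above its expected value, i.e. took a bet that is bad on
average.  The headline table compares the prevalence of both extremes in
the bottom (and top) tail of each resource distribution against the rest
of the sample, with Pearson chi-squared tests (2x2, no continuity
correction) and variance contrasts.  A parallel table for time
discounting (high = all immediate choices, low = none) serves as a
specificity control: the threshold account predicts elevated *high*
discounting among the poorest, but not elevated *low* discounting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from desperation.panel import STRAIN_LEVELS

__all__ = [
    "classify_extremes",
    "extreme_prevalence_table",
    "mean_resources_by_count",
    "strain_group_summary",
    "discounting_contrast",
    "consistency_by_resources",
]


def classify_extremes(risk_count) -> str | np.ndarray:
    """'avoider' (0 bets), 'taker' (> 4 bets) or 'neither'."""
    arr = np.asarray(risk_count)
    if np.any((arr < 0) | (arr > 7)):
        raise ValueError("risk_count must lie in 0..7")
    out = np.where(arr == 0, "avoider", np.where(arr >= 5, "taker", "neither"))
    return out.item() if out.ndim == 0 else out


def chi2_2x2(in_class_a: int, n_a: int, in_class_b: int, n_b: int):
    """Pearson chi-squared (df=1, no continuity correction) for a binary
    outcome across two groups; returns (statistic, p)."""
    table = np.array(
        [[in_class_a, n_a - in_class_a], [in_class_b, n_b - in_class_b]], float
    )
    if np.any(table < 0):
        raise ValueError("negative cell counts")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan"), float("nan")  # degenerate margin
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _category_row(counts: np.ndarray, full_counts: np.ndarray, label: str) -> dict:
    cls = classify_extremes(counts)
    row = {
        "category": label,
        "pct_takers": 100.0 * np.mean(cls == "taker"),
        "pct_avoiders": 100.0 * np.mean(cls == "avoider"),
        "mean_count": float(np.mean(counts)),
        "var_count": float(np.var(counts, ddof=1)) if len(counts) > 1 else np.nan,
        "n": int(len(counts)),
    }
    full_var = np.var(full_counts, ddof=1)
    row["var_ratio_vs_full"] = row["var_count"] / full_var if full_var > 0 else np.nan
    return row


def _tail_tests(row: dict, tail_counts, rest_counts) -> dict:
    tail_cls = classify_extremes(tail_counts)
    rest_cls = classify_extremes(rest_counts)
    for cls_name in ("avoider", "taker"):
        stat, p = chi2_2x2(
            int(np.sum(tail_cls == cls_name)),
            len(tail_counts),
            int(np.sum(rest_cls == cls_name)),
            len(rest_counts),
        )
        row[f"chi2_{cls_name}"] = stat
        row[f"p_{cls_name}"] = p
    return row


def _prevalence_table(
    panel: pd.DataFrame, count_col: str, tail_pct: float, tails=("bottom", "top")
) -> pd.DataFrame:
    if not 0 < tail_pct <= 50:
        raise ValueError("tail_pct must lie in (0, 50]")
    df = panel.dropna(subset=[count_col])
    full = df[count_col].to_numpy(dtype=float)
    if len(full) == 0:
        raise ValueError("no usable observations")
    rows = [_category_row(full, full, "full sample")]
    for var in ("objective_resources", "subjective_resources"):
        sub = df.dropna(subset=[var])
        r = sub[var].to_numpy(dtype=float)
        y = sub[count_col].to_numpy(dtype=float)
        for tail in tails:
            if tail == "bottom":
                thr = np.percentile(r, tail_pct)
                mask = r <= thr
            else:
                thr = np.percentile(r, 100 - tail_pct)
                mask = r >= thr
            if mask.sum() == 0:
                raise ValueError(f"empty {tail} tail for {var}")
            label = f"{tail} {tail_pct:g}% {var.split('_')[0]}"
            row = _category_row(y[mask], full, label)
            rows.append(_tail_tests(row, y[mask], y[~mask]))
    return pd.DataFrame(rows).set_index("category")


def extreme_prevalence_table(panel: pd.DataFrame, tail_pct: float = 5.0) -> pd.DataFrame:
    """Prevalence of risk avoiders/takers in resource tails vs the rest.

    Observation-level (pooled over waves); percentages, means, variances,
    chi-squared tests against the rest of the sample, and the variance
    ratio against the full sample.
    """
    return _prevalence_table(panel, "risk_count", tail_pct)


def mean_resources_by_count(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean (and s.e.) of each resource measure per bet count, with counts
    6 and 7 pooled into one bin."""
    df = panel.dropna(subset=["risk_count"])
    bins = df["risk_count"].clip(upper=6).astype(int)
    labels = {6: "6-7"}
    rows = []
    for b in sorted(bins.unique()):
        sub = df[bins == b]
        row = {"count_bin": labels.get(b, str(b)), "n": len(sub)}
        for var in ("objective_resources", "subjective_resources"):
            vals = sub[var].dropna()
            row[f"mean_{var}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"se_{var}"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("count_bin")


def strain_group_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean, variance and n of risk counts per financial-strain answer."""
    if "financial_strain" not in panel.columns:
        raise ValueError("panel has no financial_strain column")
    g = panel.groupby("financial_strain", observed=False)["risk_count"]
    out = pd.DataFrame(
        {"mean_count": g.mean(), "var_count": g.var(ddof=1), "n": g.size()}
    )
    return out.reindex([s for s in STRAIN_LEVELS if s in out.index])


def discounting_contrast(panel: pd.DataFrame, tail_pct: float = 5.0) -> pd.DataFrame:
    """Extreme time-discounting prevalence table, same layout as the risk
    table: 'high' discounters chose all 7 immediate rewards, 'low'
    discounters none."""
    if "discount_count" not in panel.columns:
        raise ValueError("panel has no discount_count column")
    df = panel.dropna(subset=["discount_count"])
    full = df["discount_count"].to_numpy(dtype=float)
    if len(full) == 0:
        raise ValueError("no usable observations")

    def row_for(counts, label):
        r = {
            "category": label,
            "pct_high": 100.0 * np.mean(counts == 7),
            "pct_low": 100.0 * np.mean(counts == 0),
            "mean_count": float(np.mean(counts)),
            "var_count": float(np.var(counts, ddof=1)) if len(counts) > 1 else np.nan,
            "n": int(len(counts)),
        }
        fv = np.var(full, ddof=1)
        r["var_ratio_vs_full"] = r["var_count"] / fv if fv > 0 else np.nan
        return r

    rows = [row_for(full, "full sample")]
    for var in ("objective_resources", "subjective_resources"):
        sub = df.dropna(subset=[var])
        r = sub[var].to_numpy(dtype=float)
        y = sub["discount_count"].to_numpy(dtype=float)
        thr = np.percentile(r, tail_pct)
        mask = r <= thr
        if mask.sum() == 0:
            raise ValueError(f"empty bottom tail for {var}")
        row = row_for(y[mask], f"bottom {tail_pct:g}% {var.split('_')[0]}")
        for cls_name, target in (("high", 7), ("low", 0)):
            stat, p = chi2_2x2(
                int(np.sum(y[mask] == target)),
                int(mask.sum()),
                int(np.sum(y[~mask] == target)),
                int((~mask).sum()),
            )
            row[f"chi2_{cls_name}"] = stat
            row[f"p_{cls_name}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def consistency_by_resources(panel: pd.DataFrame) -> pd.DataFrame:
    """Point-biserial correlation of battery consistency with each
    resource measure."""
    rows = []
    flag = panel["consistent"].astype(float)
    for var in ("objective_resources", "subjective_resources"):
        sub = pd.DataFrame({"flag": flag, "r": panel[var]}).dropna()
        if sub["flag"].nunique() < 2:
            rows.append({"resource": var, "r": np.nan, "p": np.nan, "n": len(sub),
                         "note": "consistency flag has no variance"})
            continue
        r, p = stats.pearsonr(sub["flag"], sub["r"])
        rows.append({"resource": var, "r": float(r), "p": float(p), "n": len(sub),
                     "note": ""})
    return pd.DataFrame(rows).set_index("resource")
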