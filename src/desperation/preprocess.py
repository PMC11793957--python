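"""Derived analysis variables from raw panel rows.

Two resource measures are built per observation:

- *objective resources*: ``log2(income + 1) - log2(costs + 1)``, the log
  of the income-to-unavoidable-costs ratio.  0 means income just covers
  costs, 1 means income is twice costs; negative values mean costs
  exceeded income that month.
- *subjective resources*: ``sqrt(300 - (item1 + item2 + item3))``, the
  reverse-coded sum of the three 0-100 insecurity items, square-rooted to
  tame the right skew of near-zero worriers.

Risk taking is the number of gambles chosen across the seven-rung ladder
(0-7); time discounting is the number of immediate choices (0-7).  A
battery is *consistent* when no gamble refused against a small sure amount
coexists with a gamble accepted against a larger one, i.e. when the choice
vector is a cutoff pattern.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from desperation.panel import DELAY_COLS, GAMBLE_COLS, ITEM_COLS, STRAIN_LEVELS

__all__ = [
    "objective_resources",
    "subjective_resources",
    "risk_count",
    "consistency_flag",
    "discount_count",
    "preprocess_panel",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    ["participant_id", "wave", "age", "gender", "income", "costs"]
    + ITEM_COLS
    + GAMBLE_COLS
    + DELAY_COLS
    + ["financial_strain"]
)


def objective_resources(income, costs):
    """log2 income-to-costs ratio (with +1 euro guard against zeros)."""
    income = np.asarray(income, dtype=float)
    costs = np.asarray(costs, dtype=float)
    if np.any(income < 0) or np.any(costs < 0):
        raise ValueError("income and costs must be non-negative")
    out = np.log2(income + 1.0) - np.log2(costs + 1.0)
    return float(out) if out.ndim == 0 else out


def subjective_resources(item1, item2, item3):
    """Reverse-coded, square-rooted sum of the three insecurity items."""
    items = np.stack(
        [np.asarray(v, dtype=float) for v in (item1, item2, item3)], axis=0
    )
    if np.any(items < 0) or np.any(items > 100):
        raise ValueError("subjective items must lie in [0, 100]")
    out = np.sqrt(300.0 - items.sum(axis=0))
    return float(out) if out.ndim == 0 else out


def _check_choices(choices) -> np.ndarray:
    arr = np.asarray(choices, dtype=float)
    if arr.shape[-1] != 7:
        raise ValueError("a battery has exactly 7 choices")
    if not np.isin(arr[np.isfinite(arr)], (0, 1)).all():
        raise ValueError("choices must be binary")
    return arr


def risk_count(choices) -> int:
    """Number of gamble choices across the ladder."""
    arr = _check_choices(choices)
    if np.isnan(arr).any():
        raise ValueError("battery contains missing choices")
    return int(arr.sum())


def consistency_flag(choices) -> bool:
    """True unless the gamble was refused against some sure amount but
    accepted against a larger one (a dominated reversal)."""
    arr = _check_choices(choices).astype(int)
    return bool(np.all(np.diff(arr) <= 0))


def discount_count(choices) -> int:
    """Number of immediate choices across the delay ladder."""
    return risk_count(choices)


def preprocess_panel(raw: pd.DataFrame) -> pd.DataFrame:
    """Row-wise derivations for a whole raw panel.

    Returns the processed table with one row per observation whose gamble
    battery is complete (rows with missing batteries are dropped and
    logged).  Age is z-scored within the analysis sample.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"panel is missing required column(s): {missing_cols}")
    if raw.empty:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "wave",
                "age",
                "age_z",
                "gender",
                "woman",
                "financial_strain",
                "objective_resources",
                "subjective_resources",
                "risk_count",
                "consistent",
                "discount_count",
            ]
        )

    df = raw.copy()
    gam = df[GAMBLE_COLS].to_numpy(dtype=float)
    keep = ~np.isnan(gam).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d rows with incomplete gamble batteries", n_dropped)
    df = df.loc[keep].reset_index(drop=True)
    gam = df[GAMBLE_COLS].to_numpy(dtype=int)

    strain = df["financial_strain"]
    bad_strain = ~strain.isin(STRAIN_LEVELS)
    if bad_strain.any():
        raise ValueError(
            f"unknown financial_strain value(s): {sorted(strain[bad_strain].unique())}"
        )

    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "wave": df["wave"],
            "age": df["age"].astype(float),
            "gender": df["gender"],
            "woman": (df["gender"] == "woman").astype(int),
            "financial_strain": pd.Categorical(
                strain, categories=list(STRAIN_LEVELS), ordered=True
            ),
            "objective_resources": objective_resources(df["income"], df["costs"]),
            "subjective_resources": subjective_resources(
                df[ITEM_COLS[0]], df[ITEM_COLS[1]], df[ITEM_COLS[2]]
            ),
            "risk_count": gam.sum(axis=1),
            "consistent": (np.diff(gam, axis=1) <= 0).all(axis=1),
        }
    )
    out["age_z"] = (out["age"] - out["age"].mean()) / out["age"].std()

    # delay battery handled separately: its gaps do not cost risk rows
    dly = df[DELAY_COLS].to_numpy(dtype=float)
    dly_ok = ~np.isnan(dly).any(axis=1)
    out["discount_count"] = np.where(dly_ok, np.nansum(dly, axis=1), np.nan)

    neg_share = float((out["objective_resources"] < 0).mean())
    incons_share = float((~out["consistent"]).mean())
    logger.info(
        "processed %d rows: %.1f%% negative objective resources, "
        "%.1f%% inconsistent batteries",
        len(out),
        100 * neg_share,
        100 * incons_share,
    )
    return out
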