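"""Desperation-threshold utility model and certainty-equivalent machinery.

The model assumes that people try to keep their resources above a critical
level representing basic needs (the *desperation threshold*).  Utility is a
sigmoid of resources around the threshold, plus a gentle linear term above
it:

    U(r) = sigmoid(u) + (u / 50) * 1[u > 0],    u = (r - threshold) / scale

The sigmoid makes utility convex below the threshold (little left to lose,
so gambles look good) and concave just above it (much to lose, so gambles
look bad); far above the threshold utility is effectively linear and the
agent is risk neutral.  Risk attitude is summarised by the certainty
equivalent (CE) of a reference gamble — the sure amount valued equally to
it.  CE above the gamble's expected value means risk taking; below, risk
avoidance.

One sigmoid unit corresponds to ``sigmoid_scale`` euros (default 100), a
scaling under which the switch from risk avoidance to risk taking for the
default 50% x 800 gamble occurs close to 400 euros below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import bisect
from scipy.special import expit

__all__ = [
    "UtilityModel",
    "LinearUtility",
    "GambleTask",
    "NoisyObservationConfig",
    "CurvePoint",
    "utility",
    "gamble_expected_utility",
    "certainty_equivalent",
    "ce_curve",
    "ce_curve_frame",
    "predicted_choices",
    "predicted_bet_count",
    "simulate_noisy_scatter",
]

CE_TOL = 0.01  # euros; absolute tolerance of the bisection CE solver


@dataclass(frozen=True)
class UtilityModel:
    """Sigmoid-plus-linear utility with a desperation threshold.

    Parameters
    ----------
    threshold_location : float
        Resource level (euros) of the threshold; utility equals 0.5 there.
    sigmoid_scale : float
        Euros per sigmoid unit; controls how wide the steep region is.
    linear_slope : float
        Utility gained per sigmoid unit of resources above the threshold.
    """

    threshold_location: float = 0.0
    sigmoid_scale: float = 100.0
    linear_slope: float = 1.0 / 50.0

    def utility(self, r):
        r = _check_resources(r)
        u = (r - self.threshold_location) / self.sigmoid_scale
        return expit(u) + self.linear_slope * u * (u > 0)


@dataclass(frozen=True)
class LinearUtility:
    """Risk-neutral benchmark: utility strictly proportional to resources."""

    slope: float = 1.0 / 5000.0

    def utility(self, r):
        r = _check_resources(r)
        return self.slope * r


@dataclass(frozen=True)
class GambleTask:
    """The elicitation battery: one gamble versus a ladder of sure amounts."""

    win_amount: float = 800.0
    win_probability: float = 0.5
    safe_amounts: tuple = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0)

    def __post_init__(self):
        if not 0 < self.win_probability < 1:
            raise ValueError("win_probability must lie strictly in (0, 1)")
        amounts = tuple(float(a) for a in self.safe_amounts)
        if any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise ValueError("safe_amounts must be strictly increasing")
        object.__setattr__(self, "safe_amounts", amounts)

    @property
    def risk_neutral_value(self) -> float:
        return self.win_probability * self.win_amount


@dataclass(frozen=True)
class NoisyObservationConfig:
    """Settings for the noisy-observation scatter of resources vs CE."""

    resource_noise_sd: float = 500.0
    ce_noise_sd: float = 50.0
    n_agents: int = 5000
    resource_range: tuple = (-800.0, 800.0)
    seed: int = 0

    def __post_init__(self):
        if self.resource_noise_sd < 0 or self.ce_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")


@dataclass(frozen=True)
class CurvePoint:
    resources: float
    certainty_equivalent: float
    regime: str  # risk_taking | risk_neutral | risk_avoidance


def _check_resources(r):
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("resources must be finite")
    return arr if arr.ndim else float(arr)


def utility(r, model: UtilityModel | LinearUtility = UtilityModel()):
    """Utility of holding ``r`` euros under ``model`` (vectorised)."""
    return model.utility(r)


def gamble_expected_utility(r, model=UtilityModel(), task: GambleTask = GambleTask()):
    """Expected utility of the gamble for an agent currently holding ``r``."""
    p = task.win_probability
    return p * model.utility(np.asarray(r, dtype=float) + task.win_amount) + (
        1.0 - p
    ) * model.utility(r)


def certainty_equivalent(
    r: float, model=UtilityModel(), task: GambleTask = GambleTask()
) -> float:
    """Sure amount ``c`` with ``U(r + c) = E[U(gamble at r)]``.

    Solved by bisection on [0, win_amount] to an absolute tolerance of
    0.01 euros; utility is strictly increasing so the root is unique.
    """
    r = float(_check_resources(r))
    eu = float(gamble_expected_utility(r, model, task))

    def f(c):
        return float(model.utility(r + c)) - eu

    lo, hi = 0.0, task.win_amount
    if f(lo) >= 0:
        return lo
    if f(hi) <= 0:
        return hi
    return float(bisect(f, lo, hi, xtol=CE_TOL))


def _regime(ce: float, neutral_value: float, atol: float) -> str:
    if ce > neutral_value + atol:
        return "risk_taking"
    if ce < neutral_value - atol:
        return "risk_avoidance"
    return "risk_neutral"


def ce_curve(
    model=UtilityModel(),
    task: GambleTask = GambleTask(),
    r_grid=None,
    neutral_atol: float = 1.0,
) -> list[CurvePoint]:
    """Certainty equivalent along a grid of resource levels.

    Each point is labelled with its risk regime relative to the gamble's
    risk-neutral value, using ``neutral_atol`` euros of slack for the
    neutral band.
    """
    if r_grid is None:
        r_grid = np.arange(-800.0, 810.0, 10.0)
    grid = np.asarray(list(r_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("r_grid must be non-empty")
    _check_resources(grid)
    rnv = task.risk_neutral_value
    points = []
    for r in grid:
        ce = certainty_equivalent(float(r), model, task)
        points.append(CurvePoint(float(r), ce, _regime(ce, rnv, neutral_atol)))
    return points


def ce_curve_frame(model=UtilityModel(), task=GambleTask(), r_grid=None) -> pd.DataFrame:
    pts = ce_curve(model, task, r_grid)
    return pd.DataFrame(
        {
            "resources": [p.resources for p in pts],
            "certainty_equivalent": [p.certainty_equivalent for p in pts],
            "regime": [p.regime for p in pts],
        }
    )


def regime_switch_point(
    model=UtilityModel(), task: GambleTask = GambleTask(), lo=-800.0, hi=0.0
) -> float:
    """Resource level where the CE crosses the gamble's risk-neutral value.

    Located by bisection on ``CE(r) - risk_neutral_value`` over [lo, hi];
    for the default model this is the switch from risk taking (below) to
    risk avoidance (above), a few hundred euros below the threshold.
    """
    rnv = task.risk_neutral_value

    def g(r):
        return certainty_equivalent(r, model, task) - rnv

    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise ValueError("CE curve does not cross the risk-neutral value on [lo, hi]")
    return float(bisect(g, lo, hi, xtol=0.5))


def predicted_choices(
    r: float,
    model=UtilityModel(),
    task: GambleTask = GambleTask(),
    tremble: float = 0.0,
    rng=None,
) -> np.ndarray:
    """Binary choice vector over the safe ladder (1 = gamble chosen).

    Without trembling the gamble is chosen against sure amount ``x``
    exactly when its expected utility strictly exceeds ``U(r + x)``, which
    yields a cutoff (non-increasing) pattern.  With ``tremble`` > 0 each of
    the choices is flipped independently with that probability.
    """
    if not 0 <= tremble < 0.5:
        raise ValueError("tremble must lie in [0, 0.5)")
    eu = float(gamble_expected_utility(r, model, task))
    choices = np.array(
        [eu > float(model.utility(r + x)) for x in task.safe_amounts], dtype=int
    )
    if tremble > 0:
        if rng is None:
            raise ValueError("a seeded rng is required when tremble > 0")
        rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
        flips = rng.random(len(choices)) < tremble
        choices = np.where(flips, 1 - choices, choices)
    return choices


def predicted_bet_count(
    r: float,
    model=UtilityModel(),
    task: GambleTask = GambleTask(),
    tremble: float = 0.0,
    rng=None,
) -> int:
    """Number of gambles chosen across the ladder (0..7 by default)."""
    return int(predicted_choices(r, model, task, tremble, rng).sum())


def simulate_noisy_scatter(
    model=UtilityModel(),
    task: GambleTask = GambleTask(),
    cfg: NoisyObservationConfig = NoisyObservationConfig(),
) -> pd.DataFrame:
    """Noisy-measurement scatter of resources against certainty equivalents.

    True resources are uniform over ``cfg.resource_range``; resources are
    observed with heavy noise and CEs with light noise.  The visible
    V-shape dissolves into a triangular scatter whose CE variance is larger
    in the low-resource half — the mechanism behind the prediction that
    risk taking varies more among the poor.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.resource_range
    true_r = rng.uniform(lo, hi, cfg.n_agents)
    ces = np.array([certainty_equivalent(float(r), model, task) for r in true_r])
    obs_r = true_r + rng.normal(0.0, cfg.resource_noise_sd, cfg.n_agents)
    obs_ce = ces + rng.normal(0.0, cfg.ce_noise_sd, cfg.n_agents)
    return pd.DataFrame(
        {
            "true_resources": true_r,
            "observed_resources": obs_r,
            "observed_ce": obs_ce,
        }
    )
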