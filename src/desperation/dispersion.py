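"""Variance-heterogeneity analyses: is risk taking more variable when
resources are low?

Three tests form one family (Holm-corrected together): an F test comparing
bet-count variance in the worst financial-strain group against everyone
else; and, for each continuous resource measure, a two-stage regression in
which squared residuals from an ordinary (no random effects) linear model
of risk taking are regressed on resources.  The first stage deliberately
omits random effects: person-level spread is exactly the variance the test
is looking for.

Also here: the threshold-sweep curve (variance below vs above a moving
resource percentile), within-person stability over waves, the
intra-class correlation of repeated counts, and Cronbach's alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from desperation.models import RandomInterceptML, holm_bonferroni

__all__ = [
    "DispersionResult",
    "SweepCurve",
    "StabilityResult",
    "variance_ratio_test",
    "squared_residual_regression",
    "variance_sweep",
    "within_person_stability",
    "icc",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class DispersionResult:
    variance_low: float
    variance_high: float
    ratio: float  # low / high
    f_stat: float
    df: tuple
    p: float  # two-sided


@dataclass
class SweepCurve:
    resource_var: str
    table: pd.DataFrame  # percentile, threshold, ratio, f, p, p_holm, n_below


@dataclass
class StabilityResult:
    resource_var: str
    slope: float  # standardized
    se: float
    p: float
    n_participants: int
    table: pd.DataFrame  # per-participant variance and mean resources


def variance_ratio_test(group_low, group_high) -> DispersionResult:
    """Two-sided F test of equal variances between two groups of counts."""
    a = np.asarray(group_low, dtype=float)
    b = np.asarray(group_high, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 or va == 0:
        raise ValueError("degenerate group: zero variance")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return DispersionResult(
        variance_low=float(va),
        variance_high=float(vb),
        ratio=float(va / vb),
        f_stat=float(f),
        df=(dfa, dfb),
        p=float(min(p, 1.0)),
    )


def _ols(X: np.ndarray, y: np.ndarray, clusters=None):
    """Least squares; classical or cluster-robust (CR1) covariance."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("rank-deficient design matrix")
    resid = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    if clusters is None:
        dof = n - k
        cov = (resid @ resid / dof) * bread
    else:
        codes, _ = pd.factorize(np.asarray(clusters))
        g = codes.max() + 1
        Xe = X * resid[:, None]
        scores = np.zeros((g, k))
        np.add.at(scores, codes, Xe)
        meat = scores.T @ scores
        corr = g / (g - 1) * (n - 1) / (n - k)
        cov = corr * bread @ meat @ bread
        dof = g - 1
    se = np.sqrt(np.diag(cov))
    t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, p, resid


def squared_residual_regression(panel: pd.DataFrame, resource_var: str):
    """Two-stage heteroscedasticity test.

    Stage 1: OLS of risk count on resources + age_z + woman, deliberately
    without random effects so between-person spread stays in the
    residuals.  Stage 2: OLS of the squared stage-1 residuals on
    resources, with cluster-robust (by participant) standard errors —
    repeated observations of one person share the same random intercept,
    so classical stage-2 errors would be anti-conservative.  Returns the
    standardized stage-2 slope, its s.e., and the two-sided p; a negative
    slope means more spread at the bottom of the distribution.
    """
    df = panel.dropna(subset=[resource_var, "risk_count", "age_z", "woman"])
    r = df[resource_var].to_numpy(dtype=float)
    y = df["risk_count"].to_numpy(dtype=float)
    X1 = np.column_stack(
        [np.ones(len(df)), r, df["age_z"].to_numpy(), df["woman"].to_numpy()]
    )
    _, _, _, resid = _ols(X1, y)
    sq = resid**2
    if sq.max() < 1e-16 or sq.std() == 0:  # constant response: no dispersion
        return 0.0, 0.0, 1.0
    rz = (r - r.mean()) / r.std()
    sqz = (sq - sq.mean()) / sq.std()
    X2 = np.column_stack([np.ones(len(df)), rz])
    clusters = (
        df["participant_id"].to_numpy() if "participant_id" in df.columns else None
    )
    beta, se, p, _ = _ols(X2, sqz, clusters=clusters)
    return float(beta[1]), float(se[1]), float(p[1])


def dispersion_family(panel: pd.DataFrame) -> pd.DataFrame:
    """The three variance-heterogeneity tests with a joint Holm correction.

    Rows: strain-group F test ('very difficult' vs rest), and squared-
    residual regressions on objective and subjective resources.
    """
    worst = panel["financial_strain"] == "very difficult"
    f_res = variance_ratio_test(
        panel.loc[worst, "risk_count"], panel.loc[~worst, "risk_count"]
    )
    rows = [
        {
            "test": "strain_variance_f",
            "statistic": f_res.f_stat,
            "estimate": f_res.ratio,
            "p": f_res.p,
        }
    ]
    for var in ("objective_resources", "subjective_resources"):
        slope, se, p = squared_residual_regression(panel, var)
        rows.append(
            {"test": f"squared_resid_{var}", "statistic": slope / se if se else 0.0,
             "estimate": slope, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_bonferroni(out["p"].to_numpy())
    return out


def variance_sweep(
    panel: pd.DataFrame,
    resource_var: str,
    pmin: float = 1.0,
    pmax: float = 50.0,
    step: float = 1.0,
) -> SweepCurve:
    """Variance ratio (below/above) as the split percentile moves from the
    low tail to the median."""
    df = panel.dropna(subset=[resource_var, "risk_count"])
    r = df[resource_var].to_numpy(dtype=float)
    y = df["risk_count"].to_numpy(dtype=float)
    rows = []
    for q in np.arange(pmin, pmax + step / 2, step):
        thr = np.percentile(r, q)
        below = r <= thr
        if below.sum() < 2 or (~below).sum() < 2:
            continue  # split too extreme at this percentile
        try:
            res = variance_ratio_test(y[below], y[~below])
        except ValueError:
            continue
        rows.append(
            {
                "percentile": float(q),
                "threshold": float(thr),
                "ratio": res.ratio,
                "f": res.f_stat,
                "p": res.p,
                "n_below": int(below.sum()),
            }
        )
    if not rows:
        raise ValueError("no feasible split in the requested percentile range")
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_bonferroni(table["p"].to_numpy())
    return SweepCurve(resource_var=resource_var, table=table)


def within_person_stability(panel: pd.DataFrame, resource_var: str) -> StabilityResult:
    """Regression of per-participant over-time count variance on mean
    resources (one data point per participant with >= 2 waves)."""
    df = panel.dropna(subset=[resource_var, "risk_count"])
    g = df.groupby("participant_id")
    per = pd.DataFrame(
        {
            "var_count": g["risk_count"].var(ddof=1),
            "mean_resources": g[resource_var].mean(),
            "n_waves": g["risk_count"].size(),
        }
    )
    per = per[per["n_waves"] >= 2].dropna()
    if len(per) < 3:
        raise ValueError("need at least 3 participants with >= 2 waves")
    if len(per) < 30:
        import warnings

        warnings.warn(f"stability regression based on only {len(per)} participants")
    v = per["var_count"].to_numpy()
    m = per["mean_resources"].to_numpy()
    if v.std() == 0:
        return StabilityResult(resource_var, 0.0, 0.0, 1.0, len(per), per)
    vz = (v - v.mean()) / v.std()
    mz = (m - m.mean()) / m.std()
    X = np.column_stack([np.ones(len(per)), mz])
    beta, se, p, _ = _ols(X, vz)
    return StabilityResult(
        resource_var=resource_var,
        slope=float(beta[1]),
        se=float(se[1]),
        p=float(p[1]),
        n_participants=len(per),
        table=per,
    )


def icc(panel: pd.DataFrame, variable: str, group_var: str = "participant_id") -> float:
    """Intra-class correlation from a random-intercept decomposition:
    between-group variance over total variance."""
    df = panel.dropna(subset=[variable])
    sizes = df.groupby(group_var)[variable].size()
    if (sizes >= 2).sum() == 0:
        raise ValueError("ICC undefined: no group has >= 2 observations")
    fitter = RandomInterceptML(df[group_var].to_numpy())
    y = df[variable].to_numpy(dtype=float)
    fit = fitter.fit(np.ones((len(df), 1)), y, names=["intercept"])
    return float(fit.sigma_b2 / (fit.sigma_b2 + fit.sigma_e2))


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Internal-consistency reliability of a multi-item scale."""
    arr = np.asarray(items, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    n, k = arr.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 rows")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero variance of the item sum")
    item_vars = arr.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))
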