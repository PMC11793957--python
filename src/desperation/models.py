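"""Confirmatory V-shape analyses: polynomial and segmented mixed models.

Both analyses model the per-wave bet count as a Gaussian outcome with a
random intercept per participant and fixed effects of standardized age and
gender, fitted by maximum likelihood (not REML) so that deviances, AICs
and likelihood-ratio tests are comparable across fixed-effect structures.

The segmented (broken-stick) model is

    risk_count = b0 + b1 (r - cp) 1[r <= cp] + b2 (r - cp) 1[r > cp]
                 + controls + u_participant + e,

with the two segments constrained to meet at the changepoint ``cp``.  The
changepoint is estimated by profiling: every admissible candidate is fitted
and the one with the smallest deviance (-2 log-likelihood) wins; ties go to
the smaller candidate.  Reported standard errors and t-tests for the
segment slopes are conditional on the selected changepoint — no correction
is applied for the search itself.

For a Gaussian random-intercept model the likelihood can be profiled down
to a one-dimensional search over the variance ratio psi = var(u)/var(e):
given psi, the model is a weighted least-squares problem solved in closed
form.  ``RandomInterceptML`` implements this directly, which makes the
changepoint grid search orders of magnitude faster than refitting a
general mixed-model routine per candidate; its log-likelihoods match
``statsmodels`` ``MixedLM`` to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RandomInterceptML",
    "MixedFit",
    "PolyFit",
    "ModelComparison",
    "SegmentedFit",
    "fit_polynomial_mixed",
    "compare_polynomials",
    "fit_segmented_mixed",
    "fit_segmented_at",
    "holm_bonferroni",
]


# ---------------------------------------------------------------------------
# profiled-likelihood random-intercept fitter
# ---------------------------------------------------------------------------


@dataclass
class MixedFit:
    """ML fit of y = X beta + u_group + e with a single random intercept."""

    params: np.ndarray
    bse: np.ndarray
    names: list
    llf: float
    sigma_b2: float  # between-group (random intercept) variance
    sigma_e2: float  # residual variance
    n_obs: int
    n_groups: int

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    def aic(self) -> float:
        # k = fixed effects + two variance parameters
        return self.deviance + 2.0 * (len(self.params) + 2)

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2.0 * stats.norm.sf(np.abs(z))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues},
            index=self.names,
        )


class RandomInterceptML:
    """Gaussian random-intercept ML via the profiled variance ratio.

    The group structure is bound once; ``fit`` can then be called
    repeatedly with different design matrices (as in a changepoint grid
    search), warm-starting the variance-ratio search.
    """

    def __init__(self, groups):
        codes, _ = pd.factorize(np.asarray(groups))
        self.codes = codes
        self.n_groups = codes.max() + 1
        self.group_n = np.bincount(codes, minlength=self.n_groups).astype(float)
        self.n = len(codes)

    def _neg2ll(self, log_psi: float, X: np.ndarray, y: np.ndarray):
        psi = np.exp(log_psi)
        theta = 1.0 - 1.0 / np.sqrt(1.0 + self.group_n * psi)
        gy = np.bincount(self.codes, weights=y, minlength=self.n_groups) / self.group_n
        ystar = y - theta[self.codes] * gy[self.codes]
        Xstar = np.empty_like(X)
        for j in range(X.shape[1]):
            gx = (
                np.bincount(self.codes, weights=X[:, j], minlength=self.n_groups)
                / self.group_n
            )
            Xstar[:, j] = X[:, j] - theta[self.codes] * gx[self.codes]
        beta, _, _, _ = np.linalg.lstsq(Xstar, ystar, rcond=None)
        # floor keeps the profile finite when a candidate fits exactly
        rss = max(float(np.sum((ystar - Xstar @ beta) ** 2)), 1e-12)
        logdet = float(np.sum(np.log1p(self.group_n * psi)))
        n2ll = self.n * np.log(2.0 * np.pi * rss / self.n) + self.n + logdet
        return n2ll, beta, rss, Xstar

    def fit(self, X, y, names=None, psi0: float = 0.5) -> MixedFit:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.std() == 0:
            raise ValueError("response has zero variance; degenerate fit")

        def obj(lp):
            return self._neg2ll(lp, X, y)[0]

        res = optimize.minimize_scalar(
            obj,
            bracket=(np.log(psi0) - 1.0, np.log(psi0)),
            method="brent",
            options={"xtol": 1e-6},
        )
        log_psi = float(res.x)
        # guard the psi -> 0 boundary (no between-group variance)
        if obj(np.log(1e-10)) < res.fun:
            log_psi = np.log(1e-10)
        n2ll, beta, rss, Xstar = self._neg2ll(log_psi, X, y)
        psi = np.exp(log_psi)
        sigma_e2 = rss / self.n
        XtX = Xstar.T @ Xstar
        cov = sigma_e2 * np.linalg.pinv(XtX)
        bse = np.sqrt(np.diag(cov))
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        return MixedFit(
            params=beta,
            bse=bse,
            names=list(names),
            llf=-0.5 * n2ll,
            sigma_b2=psi * sigma_e2,
            sigma_e2=sigma_e2,
            n_obs=self.n,
            n_groups=self.n_groups,
        )


# ---------------------------------------------------------------------------
# polynomial mixed models
# ---------------------------------------------------------------------------


class OrthoPoly:
    """Orthonormal polynomial basis of a single predictor (poly()-style)."""

    def __init__(self, x: np.ndarray, degree: int):
        if degree < 1:
            raise ValueError("degree must be >= 1")
        self.degree = degree
        self.mu = float(np.mean(x))
        self.sd = float(np.std(x))
        z = (x - self.mu) / self.sd
        V = np.vander(z, degree + 1, increasing=True)
        Q, R = np.linalg.qr(V)
        self.Rinv = np.linalg.inv(R)
        norms = np.linalg.norm(Q, axis=0)
        self.scale = norms
        self.basis = Q[:, 1:] / norms[1:]

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        z = (np.asarray(x_new, dtype=float) - self.mu) / self.sd
        V = np.vander(z, self.degree + 1, increasing=True)
        Q = V @ self.Rinv
        return Q[:, 1:] / self.scale[1:]


@dataclass
class PolyFit:
    degree: int
    fit: MixedFit
    resource_var: str
    poly: OrthoPoly
    resource_range: tuple
    resource_median: float
    control_means: dict

    @property
    def aic(self) -> float:
        return self.fit.aic()

    @property
    def llf(self) -> float:
        return self.fit.llf

    def predict_curve(self, r_grid) -> np.ndarray:
        """Fitted mean count along ``r_grid`` at average controls."""
        r_grid = np.asarray(r_grid, dtype=float)
        B = self.poly.transform(r_grid)
        beta = self.fit.params
        base = beta[0] + B @ beta[1 : 1 + self.degree]
        ctrl = sum(
            beta[1 + self.degree + j] * v
            for j, v in enumerate(self.control_means.values())
        )
        return base + ctrl

    def inflection_points(self) -> np.ndarray:
        """Real roots of the fitted curve's second derivative inside the
        observed resource range."""
        if self.degree < 3:
            return np.array([])
        lo, hi = self.resource_range
        grid = np.linspace(lo, hi, self.degree + 1)
        coefs = np.polyfit(grid, self.predict_curve(grid), self.degree)
        d2 = np.polyder(np.poly1d(coefs), 2)
        roots = d2.roots
        real = roots[np.abs(roots.imag) < 1e-8].real
        return np.sort(real[(real >= lo) & (real <= hi)])

    def inflection_in_lower_half(self) -> bool:
        pts = self.inflection_points()
        return bool(np.any(pts < self.resource_median))


def _design_controls(panel: pd.DataFrame):
    age_z = panel["age_z"].to_numpy(dtype=float)
    woman = panel["woman"].to_numpy(dtype=float)
    return {"age_z": age_z, "woman": woman}


def _clean(panel: pd.DataFrame, resource_var: str) -> pd.DataFrame:
    cols = ["participant_id", resource_var, "risk_count", "age_z", "woman"]
    return panel.dropna(subset=[c for c in cols if c in panel.columns])


def fit_polynomial_mixed(
    panel: pd.DataFrame, resource_var: str, degree: int
) -> PolyFit:
    """Random-intercept polynomial regression of risk count on resources."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    df = _clean(panel, resource_var)
    r = df[resource_var].to_numpy(dtype=float)
    y = df["risk_count"].to_numpy(dtype=float)
    poly = OrthoPoly(r, degree)
    controls = _design_controls(df)
    X = np.column_stack(
        [np.ones(len(df)), poly.basis] + [v for v in controls.values()]
    )
    names = (
        ["intercept"]
        + [f"poly{j}" for j in range(1, degree + 1)]
        + list(controls.keys())
    )
    fitter = RandomInterceptML(df["participant_id"].to_numpy())
    fit = fitter.fit(X, y, names=names)
    return PolyFit(
        degree=degree,
        fit=fit,
        resource_var=resource_var,
        poly=poly,
        resource_range=(float(r.min()), float(r.max())),
        resource_median=float(np.median(r)),
        control_means={k: float(v.mean()) for k, v in controls.items()},
    )


@dataclass
class ModelComparison:
    fits: dict  # degree -> PolyFit
    aic_table: pd.DataFrame
    lrt_table: pd.DataFrame
    selected_degree: int


def compare_polynomials(
    panel: pd.DataFrame, resource_var: str, max_degree: int = 5
) -> ModelComparison:
    """AIC table over polynomial degrees plus likelihood-ratio tests of each
    higher degree against the linear model."""
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    fits, errors = {}, {}
    for d in range(1, max_degree + 1):
        try:
            fits[d] = fit_polynomial_mixed(panel, resource_var, d)
        except Exception as exc:  # keep other degrees alive
            errors[d] = str(exc)
    if 1 not in fits:
        raise RuntimeError(f"linear baseline failed: {errors.get(1)}")
    aic = pd.DataFrame(
        {
            "degree": list(fits),
            "aic": [f.aic for f in fits.values()],
            "loglik": [f.llf for f in fits.values()],
        }
    ).set_index("degree")
    rows = []
    ll1 = fits[1].llf
    for d, f in fits.items():
        if d == 1:
            continue
        lr = max(0.0, 2.0 * (f.llf - ll1))
        df_diff = d - 1
        rows.append(
            {
                "degree": d,
                "lr_stat": lr,
                "df": df_diff,
                "p": float(stats.chi2.sf(lr, df_diff)),
            }
        )
    lrt = pd.DataFrame(rows).set_index("degree") if rows else pd.DataFrame()
    selected = int(aic["aic"].idxmin())
    return ModelComparison(fits, aic, lrt, selected)


# ---------------------------------------------------------------------------
# segmented mixed models
# ---------------------------------------------------------------------------


@dataclass
class SegmentedFit:
    cp: float
    beta0: float
    beta1: float  # slope for r <= cp
    beta2: float  # slope for r > cp
    se: dict
    pvalues: dict
    controls: dict
    scaled: dict  # slopes per s.d. of the resource variable
    deviance: float
    llf: float
    sigma_b2: float
    sigma_e2: float
    share_below: float
    resource_var: str
    profile: pd.DataFrame | None = None

    def coef_table(self) -> pd.DataFrame:
        rows = {
            "beta0": (self.beta0, self.se["beta0"], np.nan),
            "beta1": (self.beta1, self.se["beta1"], self.pvalues["beta1"]),
            "beta2": (self.beta2, self.se["beta2"], self.pvalues["beta2"]),
        }
        for k, (c, s, p) in self.controls.items():
            rows[k] = (c, s, p)
        return pd.DataFrame(rows, index=["coef", "se", "p"]).T


def _segmented_design(r: np.ndarray, cp: float, controls: dict):
    below = r <= cp
    x1 = np.where(below, r - cp, 0.0)
    x2 = np.where(~below, r - cp, 0.0)
    X = np.column_stack(
        [np.ones(len(r)), x1, x2] + [v for v in controls.values()]
    )
    names = ["beta0", "beta1", "beta2"] + list(controls.keys())
    return X, names, float(below.mean())


def _segmented_result(
    fit: MixedFit, cp, share_below, resource_var, r_sd, profile=None
) -> SegmentedFit:
    p = fit.pvalues
    ctrl = {
        name: (float(fit.params[i]), float(fit.bse[i]), float(p[i]))
        for i, name in enumerate(fit.names)
        if name not in ("beta0", "beta1", "beta2")
    }
    idx = {n: i for i, n in enumerate(fit.names)}
    return SegmentedFit(
        cp=float(cp),
        beta0=float(fit.params[idx["beta0"]]),
        beta1=float(fit.params[idx["beta1"]]),
        beta2=float(fit.params[idx["beta2"]]),
        se={k: float(fit.bse[idx[k]]) for k in ("beta0", "beta1", "beta2")},
        pvalues={k: float(p[idx[k]]) for k in ("beta1", "beta2")},
        controls=ctrl,
        scaled={
            "beta1": float(fit.params[idx["beta1"]] * r_sd),
            "beta2": float(fit.params[idx["beta2"]] * r_sd),
        },
        deviance=fit.deviance,
        llf=fit.llf,
        sigma_b2=fit.sigma_b2,
        sigma_e2=fit.sigma_e2,
        share_below=share_below,
        resource_var=resource_var,
        profile=profile,
    )


def _admissible(r: np.ndarray, candidates: np.ndarray, min_side: int) -> np.ndarray:
    keep = []
    for cp in candidates:
        n_below = int((r <= cp).sum())
        if min_side <= n_below <= len(r) - min_side:
            keep.append(cp)
    return np.asarray(keep)


def candidate_grid(
    r: np.ndarray, grid: str = "percentile", n_points: int = 199, min_side: int = 20
) -> np.ndarray:
    """Candidate changepoints: an evenly spaced percentile grid (default)
    or every unique observed value, restricted to candidates leaving at
    least ``min_side`` observations on each side."""
    r = np.asarray(r, dtype=float)
    if grid == "percentile":
        qs = np.linspace(0.5, 99.5, n_points)
        cands = np.unique(np.percentile(r, qs))
    elif grid == "observed":
        cands = np.unique(r)
    else:
        cands = np.unique(np.asarray(grid, dtype=float))
    cands = _admissible(r, cands, min_side)
    if cands.size == 0:
        raise ValueError(
            f"no admissible changepoint candidates (min_side={min_side})"
        )
    return cands


def fit_segmented_at(
    panel: pd.DataFrame, resource_var: str, cp: float, min_side: int = 20
) -> SegmentedFit:
    """Segmented random-intercept fit at a fixed changepoint."""
    df = _clean(panel, resource_var)
    r = df[resource_var].to_numpy(dtype=float)
    n_below = int((r <= cp).sum())
    if not min_side <= n_below <= len(r) - min_side:
        raise ValueError(
            f"changepoint {cp} leaves fewer than min_side={min_side} "
            "observations on one side"
        )
    controls = _design_controls(df)
    X, names, share = _segmented_design(r, cp, controls)
    fitter = RandomInterceptML(df["participant_id"].to_numpy())
    fit = fitter.fit(X, df["risk_count"].to_numpy(dtype=float), names=names)
    return _segmented_result(fit, cp, share, resource_var, float(r.std()))


def fit_segmented_mixed(
    panel: pd.DataFrame,
    resource_var: str,
    grid: str = "percentile",
    n_points: int = 199,
    min_side: int = 20,
) -> SegmentedFit:
    """Maximum-likelihood changepoint search over a candidate grid.

    Every admissible candidate is fitted by ML; the minimum-deviance fit is
    returned together with the full deviance profile.  Equal deviances are
    broken toward the smaller changepoint.
    """
    df = _clean(panel, resource_var)
    r = df[resource_var].to_numpy(dtype=float)
    y = df["risk_count"].to_numpy(dtype=float)
    controls = _design_controls(df)
    cands = candidate_grid(r, grid, n_points, min_side)
    fitter = RandomInterceptML(df["participant_id"].to_numpy())
    best = None
    psi0 = 0.5
    profile_rows = []
    for cp in cands:
        X, names, share = _segmented_design(r, cp, controls)
        try:
            fit = fitter.fit(X, y, names=names, psi0=psi0)
        except (np.linalg.LinAlgError, ValueError):
            continue  # skip non-converged candidate
        psi0 = max(fit.sigma_b2 / fit.sigma_e2, 1e-6)  # warm start
        profile_rows.append({"cp": float(cp), "deviance": fit.deviance})
        if best is None or fit.deviance < best[0].deviance - 1e-9:
            best = (fit, cp, share)
    if best is None:
        raise RuntimeError("no changepoint candidate converged")
    profile = pd.DataFrame(profile_rows)
    fit, cp, share = best
    return _segmented_result(
        fit, cp, share, resource_var, float(r.std()), profile=profile
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm's step-down adjusted p-values, in the input order.

    Sorted ascending, the i-th smallest raw p is multiplied by (m - i);
    running maxima enforce monotonicity and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
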