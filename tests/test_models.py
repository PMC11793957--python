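"""Mixed models: fitter correctness, changepoint search, Holm correction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from desperation.models import (
    OrthoPoly,
    RandomInterceptML,
    candidate_grid,
    compare_polynomials,
    fit_polynomial_mixed,
    fit_segmented_at,
    fit_segmented_mixed,
    holm_bonferroni,
)
from desperation.panel import GeneratorConfig, generate_panel
from desperation.preprocess import preprocess_panel


# ---------------------------------------------------------------- fitter


def test_fitter_matches_statsmodels_mixedlm(small_processed_panel):
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = small_processed_panel
    X = np.column_stack(
        [np.ones(len(df)), df.subjective_resources, df.age_z, df.woman]
    )
    y = df.risk_count.to_numpy(dtype=float)
    ours = RandomInterceptML(df.participant_id.to_numpy()).fit(X, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm_fit = MixedLM(y, X, groups=df.participant_id.to_numpy()).fit(reml=False)
    assert ours.llf == pytest.approx(sm_fit.llf, abs=1e-4)
    assert ours.params == pytest.approx(np.asarray(sm_fit.params)[:4], abs=1e-4)
    assert ours.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-3)


def test_fitter_zero_variance_response_errors(small_processed_panel):
    df = small_processed_panel
    X = np.ones((len(df), 1))
    with pytest.raises(ValueError):
        RandomInterceptML(df.participant_id.to_numpy()).fit(X, np.ones(len(df)))


# ------------------------------------------------------------ polynomials


def _simulate_poly_panel(seed, shape="linear", n=150, waves=4):
    """Panel with a known mean structure and a random intercept."""
    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(n), waves)
    x = rng.normal(0.0, 1.0, n * waves)
    re = rng.normal(0.0, 0.8, n)[pid]
    if shape == "linear":
        mu = 2.5 + 0.4 * x
    else:  # sharp V
        mu = 2.5 + np.where(x <= -1.0, -2.5 * (x + 1.0), 0.3 * (x + 1.0))
    y = mu + re + rng.normal(0.0, 0.9, n * waves)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "risk_count": y,
            "resources": x,
            "age_z": rng.normal(0.0, 1.0, n * waves),
            "woman": rng.integers(0, 2, n * waves),
        }
    )


def test_linear_truth_prefers_linear_model():
    picks = []
    for seed in range(8):
        panel = _simulate_poly_panel(seed, "linear")
        comp = compare_polynomials(panel, "resources", max_degree=3)
        picks.append(comp.selected_degree)
        # AIC of the richer models should rarely undercut the linear one
        assert comp.lrt_table.loc[2, "p"] > 0.001
    assert np.median(picks) == 1


def test_v_truth_prefers_nonlinear_model():
    picks = []
    for seed in range(8):
        panel = _simulate_poly_panel(seed, "v")
        comp = compare_polynomials(panel, "resources", max_degree=3)
        picks.append(comp.selected_degree)
    assert np.median(picks) >= 2


def test_polynomial_fit_reports_aic_consistently(small_processed_panel):
    fit = fit_polynomial_mixed(small_processed_panel, "subjective_resources", 2)
    k = len(fit.fit.params) + 2
    assert fit.aic == pytest.approx(-2 * fit.llf + 2 * k)


def test_max_degree_one_gives_single_row(small_processed_panel):
    comp = compare_polynomials(small_processed_panel, "subjective_resources", 1)
    assert list(comp.aic_table.index) == [1]
    assert comp.lrt_table.empty


def test_cubic_inflection_point_recovered():
    rng = np.random.default_rng(3)
    n, waves = 200, 4
    pid = np.repeat(np.arange(n), waves)
    x = rng.uniform(-2.0, 4.0, n * waves)
    y = 0.2 * x**3 + rng.normal(0.0, 0.3, n * waves) + rng.normal(0.0, 0.5, n)[pid]
    panel = pd.DataFrame(
        {
            "participant_id": pid,
            "risk_count": y,
            "resources": x,
            "age_z": rng.normal(size=n * waves),
            "woman": rng.integers(0, 2, n * waves),
        }
    )
    fit = fit_polynomial_mixed(panel, "resources", 3)
    pts = fit.inflection_points()
    assert len(pts) >= 1
    assert min(abs(pts - 0.0)) < 0.3
    assert fit.inflection_in_lower_half()  # median of U(-2,4) is ~1, kink at 0


def test_orthopoly_basis_is_orthonormal():
    rng = np.random.default_rng(0)
    x = rng.normal(size=500)
    poly = OrthoPoly(x, 3)
    G = poly.basis.T @ poly.basis
    assert np.allclose(G, np.eye(3), atol=1e-8)
    assert np.allclose(poly.transform(x), poly.basis, atol=1e-8)


# -------------------------------------------------------------- segmented


def test_segmented_recovers_planted_changepoint():
    pcts, signs = [], 0
    for seed in (31, 32, 33):
        raw = generate_panel(GeneratorConfig.strong_v(seed=seed))
        proc = preprocess_panel(raw)
        seg = fit_segmented_mixed(proc, "objective_resources", n_points=99)
        x = proc.objective_resources.to_numpy()
        pcts.append(100.0 * np.mean(x <= seg.cp))
        signs += seg.beta1 < 0 < seg.beta2
    assert abs(np.median(pcts) - 20.0) <= 5.0
    assert signs == 3


def test_segmented_linear_truth_slopes_agree():
    raw = generate_panel(GeneratorConfig.linear_truth(seed=41))
    proc = preprocess_panel(raw)
    x = proc.objective_resources.to_numpy()
    seg = fit_segmented_at(proc, "objective_resources", float(np.median(x)))
    joint_se = np.hypot(seg.se["beta1"], seg.se["beta2"])
    assert abs(seg.beta1 - seg.beta2) < 3.0 * joint_se


def test_segmented_profile_minimum_and_consistency(small_processed_panel):
    seg = fit_segmented_mixed(small_processed_panel, "subjective_resources", n_points=40)
    profile = seg.profile
    assert seg.deviance == pytest.approx(profile.deviance.min(), abs=1e-8)
    refit = fit_segmented_at(small_processed_panel, "subjective_resources", seg.cp)
    assert refit.deviance == pytest.approx(seg.deviance, abs=1e-6)
    assert refit.beta1 == pytest.approx(seg.beta1, abs=1e-8)
    # segmented model nests the linear one: its deviance cannot be worse
    lin = fit_polynomial_mixed(small_processed_panel, "subjective_resources", 1)
    assert seg.deviance <= -2 * lin.llf + 1e-6


def test_segmented_two_candidates_tie_breaks_low(small_processed_panel):
    df = small_processed_panel
    r = df.subjective_resources.to_numpy()
    cands = candidate_grid(r, "percentile", n_points=5, min_side=20)
    devs = {
        cp: fit_segmented_at(df, "subjective_resources", cp).deviance for cp in cands
    }
    seg = fit_segmented_mixed(df, "subjective_resources", n_points=5)
    assert seg.deviance == pytest.approx(min(devs.values()), abs=1e-8)
    best = min(devs, key=lambda c: (round(devs[c], 9), c))
    assert seg.cp == pytest.approx(best)


def test_segmented_min_side_enforced(small_processed_panel):
    lo = small_processed_panel.subjective_resources.min()
    with pytest.raises(ValueError):
        fit_segmented_at(small_processed_panel, "subjective_resources", lo, min_side=20)


def test_candidate_grid_infeasible_raises():
    r = np.arange(10.0)
    with pytest.raises(ValueError):
        candidate_grid(r, "observed", min_side=20)


# ------------------------------------------------------------------ Holm


def test_holm_hand_computed_cases():
    assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_bonferroni([0.2]) == pytest.approx([0.2])
    assert holm_bonferroni([0.5, 0.9]) == pytest.approx([1.0, 1.0])


def test_holm_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    for _ in range(10):
        p = rng.uniform(0, 1, size=rng.integers(2, 8))
        ours = holm_bonferroni(p)
        _, theirs, _, _ = multipletests(p, method="holm")
        assert ours == pytest.approx(theirs)


def test_holm_dominates_raw_and_bonferroni_for_minimum():
    p = np.array([0.012, 0.2, 0.03, 0.8])
    adj = holm_bonferroni(p)
    assert np.all(adj >= p)
    assert adj[np.argmin(p)] == pytest.approx(min(p.min() * len(p), 1.0))


def test_holm_rejects_invalid():
    with pytest.raises(ValueError):
        holm_bonferroni([0.5, 1.2])
    with pytest.raises(ValueError):
        holm_bonferroni([])
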