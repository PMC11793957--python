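"""Variance-heterogeneity tests, ICC and reliability."""

import numpy as np
import pandas as pd
import pytest

from desperation.dispersion import (
    cronbach_alpha,
    dispersion_family,
    icc,
    squared_residual_regression,
    variance_ratio_test,
    variance_sweep,
    within_person_stability,
)


def test_variance_ratio_identical_groups():
    x = np.array([0, 1, 2, 3, 4, 5, 6, 7] * 10, dtype=float)
    res = variance_ratio_test(x, x.copy())
    assert res.ratio == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)


def test_variance_ratio_detects_fourfold_variance():
    rng = np.random.default_rng(0)
    res = variance_ratio_test(rng.normal(0, 2, 500), rng.normal(0, 1, 500))
    assert res.ratio == pytest.approx(4.0, rel=0.2)
    assert res.p < 0.001


def test_variance_ratio_symmetry():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1.5, 80), rng.normal(0, 1, 60)
    fwd, rev = variance_ratio_test(a, b), variance_ratio_test(b, a)
    assert fwd.ratio * rev.ratio == pytest.approx(1.0)
    assert fwd.p == pytest.approx(rev.p, abs=1e-12)
    assert fwd.df == rev.df[::-1]


def test_variance_ratio_edge_and_errors():
    res = variance_ratio_test([0.0, 1.0], [0.0, 2.0])  # n=2 per side: valid
    assert res.df == (1, 1)
    with pytest.raises(ValueError):
        variance_ratio_test([1.0], [0.0, 1.0])
    with pytest.raises(ValueError):
        variance_ratio_test([1.0, 1.0], [0.0, 1.0])


def _homoscedastic_panel(seed, n=400):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "resources": rng.normal(0, 1, n),
            "risk_count": rng.normal(2.5, 1.2, n),
            "age_z": rng.normal(0, 1, n),
            "woman": rng.integers(0, 2, n),
        }
    ).assign(resources_copy=lambda d: d.resources)


def test_squared_residual_regression_null_calibration():
    slopes, rejections = [], 0
    for seed in range(60):
        panel = _homoscedastic_panel(seed)
        slope, se, p = squared_residual_regression(panel, "resources")
        slopes.append(slope)
        rejections += p < 0.05
    assert abs(np.mean(slopes)) < 0.02
    assert rejections <= 10  # ~5% nominal over 60 draws


def test_squared_residual_regression_detects_bottom_variance():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 2000
        x = rng.normal(0, 1, n)
        sd = np.where(x <= np.percentile(x, 20), 2.0, 1.0)
        y = 2.5 + 0.2 * x + rng.normal(0, sd)
        panel = pd.DataFrame(
            {
                "participant_id": np.arange(n),
                "resources": x,
                "risk_count": y,
                "age_z": rng.normal(0, 1, n),
                "woman": rng.integers(0, 2, n),
            }
        )
        slope, _, p = squared_residual_regression(panel, "resources")
        hits += (slope < 0) and (p < 0.05)
    assert hits >= 8


def test_squared_residual_constant_response():
    panel = _homoscedastic_panel(0).assign(risk_count=3.0)
    slope, se, p = squared_residual_regression(panel, "resources")
    assert slope == 0.0 and p == 1.0


def test_variance_sweep_iid_counts_flat():
    rng = np.random.default_rng(2)
    n = 4000
    panel = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "resources": rng.normal(0, 1, n),
            "risk_count": rng.integers(0, 8, n).astype(float),
        }
    )
    sweep = variance_sweep(panel, "resources")
    ratios = sweep.table.ratio
    assert 0.85 < ratios.mean() < 1.15
    assert (sweep.table.p < 0.05).mean() < 0.25  # correlated points, lenient


def test_variance_sweep_permutation_null_on_generator_data(processed_panel):
    rng = np.random.default_rng(3)
    shuffled = processed_panel.copy()
    shuffled["subjective_resources"] = rng.permutation(
        shuffled["subjective_resources"].to_numpy()
    )
    sweep = variance_sweep(shuffled, "subjective_resources")
    assert 0.9 < sweep.table.ratio.mean() < 1.1


def test_variance_sweep_generator_default_elevated(processed_panel):
    for var in ("objective_resources", "subjective_resources"):
        sweep = variance_sweep(processed_panel, var)
        assert (sweep.table.ratio > 1.0).all()
        # variance contrast grows toward the poorest tail
        t = sweep.table
        assert t.ratio.iloc[0] > t.ratio.iloc[-1]


def test_variance_sweep_single_point():
    rng = np.random.default_rng(4)
    panel = pd.DataFrame(
        {
            "participant_id": np.arange(500),
            "resources": rng.normal(0, 1, 500),
            "risk_count": rng.integers(0, 8, 500).astype(float),
        }
    )
    sweep = variance_sweep(panel, "resources", pmin=25, pmax=25)
    assert len(sweep.table) == 1


def test_dispersion_family_on_generator_data(processed_panel):
    fam = dispersion_family(processed_panel)
    assert set(fam["test"]) == {
        "strain_variance_f",
        "squared_resid_objective_resources",
        "squared_resid_subjective_resources",
    }
    assert (fam["p_holm"] >= fam["p"] - 1e-12).all()
    # the three low-resource variance signals are present in the synthetic data
    assert fam.loc[fam.test == "strain_variance_f", "estimate"].iloc[0] > 1.0
    assert (fam.loc[fam.test.str.startswith("squared"), "estimate"] < 0).all()


def test_within_person_stability_constant_counts():
    panel = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(50), 4),
            "resources": np.random.default_rng(0).normal(0, 1, 200),
            "risk_count": np.repeat(np.arange(50) % 8, 4).astype(float),
        }
    )
    res = within_person_stability(panel, "resources")
    assert res.slope == 0.0


def test_within_person_stability_negative_on_generator(processed_panel):
    res = within_person_stability(processed_panel, "subjective_resources")
    assert res.slope < 0
    assert res.p < 0.05


def test_within_person_stability_needs_repeats():
    panel = pd.DataFrame(
        {
            "participant_id": np.arange(10),
            "resources": np.random.default_rng(0).normal(0, 1, 10),
            "risk_count": np.arange(10).astype(float),
        }
    )
    with pytest.raises(ValueError):
        within_person_stability(panel, "resources")


def test_icc_extremes():
    between = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(30), 4),
            "y": np.repeat(np.arange(30, dtype=float), 4),
        }
    )
    assert icc(between, "y") > 0.99
    rng = np.random.default_rng(0)
    within = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(200), 5),
            "y": rng.normal(0, 1, 1000),
        }
    )
    assert icc(within, "y") < 0.05
    with pytest.raises(ValueError):
        icc(between.drop_duplicates("participant_id"), "y")


def test_icc_matches_pingouin(small_processed_panel):
    pingouin = pytest.importorskip("pingouin")
    df = small_processed_panel
    # balanced subset: participants with all five waves
    counts = df.groupby("participant_id").size()
    keep = counts[counts == counts.max()].index
    sub = df[df.participant_id.isin(keep)]
    ours = icc(sub, "risk_count")
    res = pingouin.intraclass_corr(
        data=sub, targets="participant_id", raters="wave", ratings="risk_count"
    )
    theirs = float(res.loc[res.Type == "ICC(1,1)", "ICC"].iloc[0])
    assert ours == pytest.approx(theirs, abs=0.02)


def test_cronbach_alpha_extremes_and_pingouin(default_panel):
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    same = pd.DataFrame({"a": rng.uniform(0, 1, 100)})
    same["b"] = same["a"]
    same["c"] = same["a"]
    assert cronbach_alpha(same) == pytest.approx(1.0)
    indep = pd.DataFrame(rng.normal(0, 1, (2000, 3)), columns=list("abc"))
    assert abs(cronbach_alpha(indep)) < 0.1
    items = default_panel[["subj_item_1", "subj_item_2", "subj_item_3"]]
    theirs = pingouin.cronbach_alpha(data=items)[0]
    assert cronbach_alpha(items) == pytest.approx(theirs, abs=1e-6)
    with pytest.raises(ValueError):
        cronbach_alpha(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))
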