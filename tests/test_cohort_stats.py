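"""Group comparisons, correlation matrices and regression reports."""

import numpy as np
import pandas as pd
import pytest

from gaitbelt.cohort_stats import (
    compare_groups,
    correlation_matrix,
    fit_linear_model,
    holm_adjust,
)
from gaitbelt.exceptions import (
    DegenerateInputError,
    ParameterError,
    SingularDesignError,
)


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        out = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out.test == "welch-t"
        assert out.p_value == pytest.approx(1.0)
        assert out.groups["a"]["mean"] == pytest.approx(2.0)

    def test_small_expected_cell_switches_to_fisher(self):
        # current-smoker counts by sarcopenia status: 6/13 vs 10/93
        values = {
            "sarcopenic": ["current"] * 6 + ["other"] * 7,
            "normal": ["current"] * 10 + ["other"] * 83,
        }
        out = compare_groups(values, "discrete", "current smoker")
        assert out.test == "fisher"
        assert out.groups["sarcopenic"]["current"] == 6

    def test_large_balanced_table_uses_chi_square(self):
        values = {
            "a": ["x"] * 40 + ["y"] * 60,
            "b": ["x"] * 55 + ["y"] * 45,
        }
        assert compare_groups(values, "discrete").test == "chi-square"

    def test_three_groups_use_anova(self):
        rng = np.random.default_rng(0)
        out = compare_groups(
            {g: rng.normal(size=20) for g in "abc"}, "continuous"
        )
        assert out.test == "anova"

    def test_unit_effect_detected_in_nearly_all_replicates(self):
        rng = np.random.default_rng(123)
        rejections = sum(
            compare_groups(
                {"a": rng.normal(0, 1, 200), "b": rng.normal(1, 1, 200)}
            ).p_value < 0.05
            for _ in range(200)
        )
        assert rejections >= 198  # power ~ 1 at d = 1, n = 200

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_groups({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups({"a": [1.0], "b": []})


class TestCorrelationMatrix:
    def test_perfect_linear_relationships(self):
        x = np.arange(10.0)
        r, p = correlation_matrix(pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x}))
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_pairwise_complete_observations(self):
        frame = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan], "y": [2, 4, 6, 8, 10.0],
             "z": [1.0, 2.5, 2.0, 4.4, 5.0]}
        )
        r, _ = correlation_matrix(frame)
        assert r.loc["x", "y"] == pytest.approx(1.0)  # NaN row dropped for the pair

    def test_affine_transform_invariance(self, rng):
        frame = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        r1, _ = correlation_matrix(frame)
        frame2 = frame.assign(a=3.0 * frame["a"] + 7.0)
        r2, _ = correlation_matrix(frame2)
        assert r1.loc["a", "b"] == pytest.approx(r2.loc["a", "b"], rel=1e-12)

    def test_sampling_interval_coverage_at_moderate_correlation(self):
        # rho = 0.5, n = 106: Fisher-z 95% interval is about [0.33, 0.64]
        rng = np.random.default_rng(7)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        inside = 0
        for _ in range(100):
            sample = rng.multivariate_normal([0, 0], cov, size=106)
            r, _ = correlation_matrix(pd.DataFrame(sample, columns=["a", "b"]))
            inside += 0.33 <= r.loc["a", "b"] <= 0.64
        assert inside >= 90

    def test_constant_variable_rejected(self):
        frame = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1, 2, 3, 4.0]})
        with pytest.raises(DegenerateInputError):
            correlation_matrix(frame)

    def test_too_few_complete_observations_rejected(self):
        frame = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ParameterError):
            correlation_matrix(frame)


class TestLinearModel:
    def test_orthogonal_predictors_have_unit_vif(self):
        # full +-1 factorial: exactly orthogonal columns
        x1 = np.array([-1, -1, 1, 1, -1, -1, 1, 1], dtype=float)
        x2 = np.array([-1, 1, -1, 1, -1, 1, -1, 1], dtype=float)
        y = 1.0 + 2 * x1 - x2 + np.array([0.1, -0.1, 0.05, 0, 0.02, -0.02, 0.03, -0.08])
        report = fit_linear_model(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert report.table["vif"].values == pytest.approx([1.0, 1.0])

    def test_noiseless_cohort_style_response_recovered(self, rng):
        n = 106
        design = pd.DataFrame(
            {
                "age": rng.normal(71.1, 7.6, n),
                "height": rng.normal(1.68, 0.06, n),
                "leg_muscle_mass": rng.normal(13.2, 1.8, n),
            }
        )
        y = (0.837 - 0.003 * design["age"] + 0.259 * design["height"]
             + 0.011 * design["leg_muscle_mass"])
        report = fit_linear_model(y, design)
        assert report.intercept == pytest.approx(0.837, abs=1e-8)
        assert report.table.loc["age", "B"] == pytest.approx(-0.003, abs=1e-8)
        assert report.table.loc["height", "B"] == pytest.approx(0.259, abs=1e-8)
        assert report.table.loc["leg_muscle_mass", "B"] == pytest.approx(0.011, abs=1e-8)
        assert report.r_squared == pytest.approx(1.0, abs=1e-10)
        assert (report.table["vif"] >= 1.0).all()

    def test_correlated_predictors_inflate_vif(self):
        # build an exact in-sample correlation of 0.9 by Gram-Schmidt, so
        # both VIFs equal the closed form 1/(1 - rho^2) ~ 5.26
        rng = np.random.default_rng(11)
        a = rng.normal(size=500)
        e = rng.normal(size=500)
        a_std = (a - a.mean()) / a.std(ddof=1)
        e_res = e - e.mean() - np.dot(e - e.mean(), a_std) * a_std / np.dot(a_std, a_std)
        e_std = e_res / e_res.std(ddof=1)
        b = 0.9 * a_std + np.sqrt(1 - 0.81) * e_std
        design = pd.DataFrame({"a": a_std, "b": b})
        y = design["a"] + design["b"] + rng.normal(0, 0.5, 500)
        report = fit_linear_model(y, design)
        assert report.table["vif"].values == pytest.approx(1 / (1 - 0.81), rel=1e-6)

    def test_vif_equals_brute_force_auxiliary_regression(self, rng):
        design = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        design["c"] += 0.7 * design["a"]
        y = design.sum(axis=1) + rng.normal(0, 1, 60)
        report = fit_linear_model(y, design)
        for column in design.columns:
            others = design.drop(columns=column)
            aux = fit_linear_model(design[column], others)
            expected = 1.0 / (1.0 - aux.r_squared)
            assert report.table.loc[column, "vif"] == pytest.approx(expected, rel=1e-9)

    def test_beta_sign_matches_b_sign(self, rng):
        design = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = 2 * design["a"] - 3 * design["b"] + rng.normal(0, 1, 40)
        table = fit_linear_model(y, design).table
        assert np.all(np.sign(table["beta"]) == np.sign(table["B"]))

    def test_single_predictor_has_unit_vif(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=20)})
        report = fit_linear_model(2 * x["a"] + rng.normal(0, 0.1, 20), x)
        assert report.table.loc["a", "vif"] == 1.0

    def test_perfect_collinearity_rejected(self, rng):
        a = rng.normal(size=30)
        design = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(SingularDesignError):
            fit_linear_model(a + rng.normal(size=30), design)

    def test_constant_predictor_rejected(self, rng):
        design = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        with pytest.raises(DegenerateInputError):
            fit_linear_model(rng.normal(size=30), design)

    def test_insufficient_observations_rejected(self, rng):
        design = pd.DataFrame(rng.normal(size=(3, 2)), columns=["a", "b"])
        with pytest.raises(ParameterError):
            fit_linear_model([1.0, 2.0, 3.0], design)


def test_holm_adjustment_is_monotone_and_conservative():
    raw = [0.01, 0.04, 0.03, 0.20]
    adjusted = holm_adjust(raw)
    assert np.all(adjusted >= np.asarray(raw))
    order = np.argsort(raw)
    assert np.all(np.diff(adjusted[order]) >= -1e-12)
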