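import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flumen.cohort_stats import (
    bland_altman,
    compare_categorical,
    compare_groups,
    correlation_matrix,
    growth_rate_and_group,
    robust_regression,
)
from flumen.io import FlumenError


class TestGrowthRateAndGroup:
    def test_no_growth_is_stable(self):
        assert growth_rate_and_group(40.0, 40.0, 2.0) == (0.0, "stable")

    def test_boundary_three_mm_per_year_is_enlarging(self):
        rate, group = growth_rate_and_group(40.0, 46.0, 2.0)
        assert rate == pytest.approx(3.0)
        assert group == "enlarging"

    def test_just_below_threshold_is_stable(self):
        rate, group = growth_rate_and_group(40.0, 45.8, 2.0)
        assert rate == pytest.approx(2.9)
        assert group == "stable"

    def test_nonpositive_interval_errors(self):
        with pytest.raises(FlumenError):
            growth_rate_and_group(40.0, 42.0, 0.0)

    @given(
        baseline=st.floats(20, 80),
        followup=st.floats(20, 80),
        interval=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_classification_is_pure_threshold_function(self, baseline, followup, interval):
        rate, group = growth_rate_and_group(baseline, followup, interval)
        assert group == ("enlarging" if rate >= 3.0 else "stable")


def two_group_table(a, b):
    return pd.DataFrame(
        {
            "value": np.concatenate([a, b]),
            "group": ["stable"] * len(a) + ["enlarging"] * len(b),
        }
    )


class TestCompareGroups:
    def test_identical_constant_groups_degenerate_p_one(self):
        table = two_group_table([5.0] * 4, [5.0] * 4)
        res = compare_groups(table, "value")
        assert res.test == "degenerate"
        assert res.p_value == 1.0

    def test_identical_distributions_large_p(self):
        x = np.arange(10.0)
        res = compare_groups(two_group_table(x, x), "value")
        assert res.p_value > 0.9

    def test_normal_samples_route_to_t_test(self):
        rng = np.random.default_rng(0)
        table = two_group_table(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        res = compare_groups(table, "value")
        assert res.test == "t"
        assert res.p_value < 0.001
        assert "mean" in res.descriptives["enlarging"]

    def test_heavy_tailed_samples_route_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        a = rng.standard_cauchy(40)
        b = rng.standard_cauchy(40) + 5
        res = compare_groups(two_group_table(a, b), "value")
        assert res.test == "mann-whitney"
        assert "median" in res.descriptives["stable"]

    def test_published_flef_group_parameters_detectable(self):
        # 10 +/- 12 (n=4) vs 49 +/- 18 (n=8): a very large effect
        rng = np.random.default_rng(42)
        a = np.maximum(rng.normal(10, 11.9, 4), 0)
        b = np.maximum(rng.normal(49, 17.9, 8), 0)
        res = compare_groups(two_group_table(a, b), "value")
        assert res.p_value < 0.05


class TestCompareCategorical:
    def test_small_expected_counts_use_fisher(self):
        table = pd.DataFrame(
            {
                "sex": ["m", "m", "m", "f", "m", "m", "f", "m", "m", "f", "m", "m"],
                "group": ["stable"] * 4 + ["enlarging"] * 8,
            }
        )
        res = compare_categorical(table, "sex")
        assert res.test == "fisher"
        assert 0 <= res.p_value <= 1

    def test_large_counts_use_chi_square(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "flag": rng.choice(["y", "n"], 200),
                "group": rng.choice(["stable", "enlarging"], 200),
            }
        )
        assert compare_categorical(table, "flag").test == "chi-square"


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        table = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0) ** 2})
        r, _ = correlation_matrix(table, ["x", "y"])
        assert r.loc["x", "x"] == 1.0

    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"x": x, "y": 2 * x})
        r, p = correlation_matrix(table, ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 1e-6

    def test_recovers_generating_correlation(self):
        # Cholesky construction at the published FLEF-growth correlation 0.78
        rng = np.random.default_rng(7)
        n, target = 500, 0.78
        z = rng.normal(size=(2, n))
        x = z[0]
        y = target * z[0] + np.sqrt(1 - target**2) * z[1]
        table = pd.DataFrame({"flef": x, "growth_rate": y})
        r, _ = correlation_matrix(table, ["flef", "growth_rate"])
        assert r.loc["flef", "growth_rate"] == pytest.approx(target, abs=0.05)

    def test_insufficient_pairs_flagged_nan(self):
        table = pd.DataFrame({"x": [1.0, 2.0, np.nan], "y": [np.nan, 1.0, 2.0]})
        r, p = correlation_matrix(table, ["x", "y"])
        assert np.isnan(r.loc["x", "y"]) and np.isnan(p.loc["x", "y"])


class TestRobustRegression:
    def test_noiseless_recovery_to_machine_precision(self):
        rng = np.random.default_rng(0)
        n = 20
        flef = rng.uniform(0, 90, n)
        diam = rng.uniform(30, 60, n)
        y = 0.23 * flef + 0.45 * diam  # published-coefficient construction
        table = pd.DataFrame({"growth_rate": y, "flef": flef, "baseline_diameter": diam})
        res = robust_regression(table)
        assert res.coefficients.loc["flef", "beta"] == pytest.approx(0.23, abs=1e-10)
        assert res.coefficients.loc["baseline_diameter", "beta"] == pytest.approx(0.45, abs=1e-10)
        assert res.adjusted_r2 == pytest.approx(1.0)

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        table = pd.DataFrame(
            {"growth_rate": rng.normal(size=15), "a": x, "b": 2 * x}
        )
        with pytest.raises(FlumenError, match="collinear.*a.*b"):
            robust_regression(table, predictors=("a", "b"))

    def test_permuting_outcome_destroys_significance(self):
        rng = np.random.default_rng(2)
        n = 40
        flef = rng.uniform(0, 90, n)
        diam = rng.uniform(30, 60, n)
        y = 0.23 * flef + 0.45 * diam + rng.normal(0, 2, n)
        pvals = []
        for _ in range(50):
            table = pd.DataFrame(
                {"growth_rate": rng.permutation(y), "flef": flef,
                 "baseline_diameter": diam}
            )
            pvals.append(robust_regression(table).coefficients.loc["flef", "p"])
        assert np.median(pvals) > 0.05

    def test_robust_and_classical_se_agree_homoskedastic(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        table = pd.DataFrame({"growth_rate": y, "x": x})
        robust = robust_regression(table, predictors=("x",), cov_type="HC1")
        import statsmodels.api as sm

        classical = sm.OLS(y, sm.add_constant(x)).fit()
        ratio = robust.coefficients.loc["x", "se"] / classical.bse[1]
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_too_few_subjects_errors(self):
        table = pd.DataFrame(
            {"growth_rate": [1.0, 2.0, 3.0], "flef": [1.0, 2.0, 3.0],
             "baseline_diameter": [4.0, 5.0, 6.0]}
        )
        with pytest.raises(FlumenError):
            robust_regression(table)


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(x, x)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(x + 2, x)
        assert res.bias == pytest.approx(2.0)
        assert res.sd == 0.0

    def test_recovers_generating_interrater_sd(self):
        # simulated two-rater FLEF with inter-rater SD 13.4
        rng = np.random.default_rng(4)
        n, sigma = 500, 13.4
        a = rng.uniform(0, 88, n)
        b = a + rng.normal(-1.6, sigma, n)
        res = bland_altman(a, b)
        assert res.sd == pytest.approx(sigma, rel=0.10)
        assert res.bias == pytest.approx(1.6, abs=2.0)
        assert res.plot_data.shape == (n, 2)

    def test_length_mismatch_errors(self):
        with pytest.raises(FlumenError):
            bland_altman(np.arange(4.0), np.arange(5.0))
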