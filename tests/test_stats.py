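"""Statistical procedures: effect sizes, regression, ANCOVA, factorial
ANOVA, MANOVA/Wilks, repeatability, normality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mpfkit.stats import (ancova_compare_lines, bland_altman, cohens_d,
                          cohens_d_from_summary, compare_groups,
                          factorial_anova, fisher_compare_correlations,
                          manova_wilks, pearson_regression, shapiro_wilk)


class TestCohensD:
    def test_identical_samples_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert cohens_d(x, x) == 0.0

    def test_sign_flip_on_swap(self, rng):
        x1 = rng.normal(1, 1, 10)
        x2 = rng.normal(0, 1, 10)
        assert cohens_d(x1, x2) == pytest.approx(-cohens_d(x2, x1))

    def test_summary_formula_equals_sample_formula(self, rng):
        x1 = rng.normal(0, 1, 9)
        x2 = rng.normal(1, 2, 13)
        d_sum = cohens_d_from_summary(x1.mean(), x1.std(ddof=1), 9,
                                      x2.mean(), x2.std(ddof=1), 13)
        assert cohens_d(x1, x2) == pytest.approx(d_sum, rel=1e-12)

    def test_equal_n_reduces_to_average_variance_form(self):
        d = cohens_d_from_summary(13.15, 0.73, 7, 9.65, 0.95, 7)
        assert d == pytest.approx(3.50 / np.sqrt((0.73**2 + 0.95**2) / 2),
                                  rel=1e-12)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_regression(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        res = pearson_regression(x, -x + 3.0)
        assert res.r == pytest.approx(-1.0)

    def test_ci_contains_estimate_and_r2_consistent(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(scale=0.3, size=30)
        res = pearson_regression(x, y)
        assert res.slope_ci[0] <= res.slope <= res.slope_ci[1]
        assert res.intercept_ci[0] <= res.intercept <= res.intercept_ci[1]
        assert res.r2 == pytest.approx(res.r ** 2, abs=5e-4)
        assert 0 <= res.p <= 1

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            pearson_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherComparison:
    def test_equal_correlations(self):
        z, p = fisher_compare_correlations(0.9, 20, 0.9, 30)
        assert z == 0.0
        assert p == 1.0

    def test_opposite_strong_correlations(self):
        _, p = fisher_compare_correlations(0.9, 50, -0.9, 50)
        assert p < 1e-6

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            fisher_compare_correlations(0.5, 3, 0.5, 10)


class TestAncova:
    def test_identical_groups_nonsignificant(self, rng):
        x = np.tile(np.arange(10.0), 2)
        y_half = 0.5 * np.arange(10.0) + 1.0 + rng.normal(0, 0.1, 10)
        y = np.tile(y_half, 2)  # group b duplicates group a exactly
        g = ["a"] * 10 + ["b"] * 10
        res = ancova_compare_lines(x, y, g)
        assert res["p_slope_diff"] >= 0.99
        assert res["p_intercept_diff"] >= 0.99

    def test_different_slopes_detected(self, rng):
        x = np.concatenate([rng.uniform(0, 10, 200)] * 2)
        g = np.array(["a"] * 200 + ["b"] * 200)
        slopes = np.where(g == "a", 0.10, 0.20)
        y = slopes * x + rng.normal(scale=0.05, size=400)
        res = ancova_compare_lines(x, y, g)
        assert res["p_slope_diff"] < 0.001

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            ancova_compare_lines([1, 2, 3], [1, 2, 3], ["a"] * 3)


class TestFactorialAnova:
    def test_one_factor_equals_squared_t(self, rng):
        y = rng.normal(size=24)
        g = np.array(["a"] * 12 + ["b"] * 12)
        res = factorial_anova(y, pd.DataFrame({"g": g}), terms=["g"])
        t, p = sps.ttest_ind(y[g == "a"], y[g == "b"], equal_var=True)
        assert res.loc["g", "F"] == pytest.approx(t ** 2, rel=1e-9)
        assert res.loc["g", "p"] == pytest.approx(p, rel=1e-9)

    def test_default_terms_are_mains_and_pairwise(self, rng):
        ft = pd.DataFrame([(a, b, c) for a in "AB" for b in "CD"
                           for c in "EF" for _ in range(3)],
                          columns=["t", "r", "m"])
        res = factorial_anova(rng.normal(size=len(ft)), ft)
        assert list(res.index) == ["t", "r", "m", "t:r", "t:m", "r:m"]

    def test_injected_main_effect_detected(self, rng):
        ft = pd.DataFrame([(a, b, c) for a in "AB" for b in "CD"
                           for c in "EF" for _ in range(7)],
                          columns=["t", "r", "m"])
        y = rng.normal(size=len(ft)) + 2.0 * (ft["t"] == "B").to_numpy()
        res = factorial_anova(y, ft)
        assert res.loc["t", "p"] < 0.001

    def test_single_level_factor_rejected(self):
        ft = pd.DataFrame({"g": ["a"] * 6})
        with pytest.raises(ValueError):
            factorial_anova(np.arange(6.0), ft)


class TestManovaWilks:
    def test_zero_between_variance_lambda_one(self):
        y = np.array([[1.0, 2.0], [3.0, 0.5], [1.0, 2.0], [3.0, 0.5],
                      [2.0, 0.0], [2.0, 0.0]])
        g = ["a", "a", "b", "b", "a", "b"]  # identical group means
        lam, f, p = manova_wilks(g, y)
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_single_response_reduces_to_anova(self, rng):
        y = rng.normal(size=20)
        g = np.array(["a"] * 10 + ["b"] * 10)
        lam, f, p = manova_wilks(g, y[:, None])
        ref = sps.f_oneway(y[g == "a"], y[g == "b"])
        assert f == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_separated_groups(self, rng):
        y = rng.normal(size=(24, 6))
        y[12:] += 5.0
        g = ["a"] * 12 + ["b"] * 12
        lam, f, p = manova_wilks(g, y)
        assert lam < 0.1
        assert p < 0.001

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        y = rng.normal(size=(30, 3))
        y[15:] += 0.8
        g = np.array(["a"] * 15 + ["b"] * 15)
        lam, f, p = manova_wilks(g, y)
        df = pd.DataFrame(y, columns=["y1", "y2", "y3"])
        df["g"] = g
        mv = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
        tbl = mv.mv_test().results["g"]["stat"]
        row = tbl.loc["Wilks' lambda"]
        assert lam == pytest.approx(float(row["Value"]), rel=1e-9)
        assert f == pytest.approx(float(row["F Value"]), rel=1e-9)
        assert p == pytest.approx(float(row["Pr > F"]), rel=1e-9, abs=1e-12)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            manova_wilks(["a", "b", "a", "b"], rng.normal(size=(4, 6)))


class TestBlandAltman:
    def test_identical_measurements(self):
        m = np.array([10.0, 11.0, 12.0, 13.0])
        res = bland_altman(m, m)
        assert res.bias == 0.0
        assert res.within_subject_cov == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_single_pair_cov_arithmetic(self):
        res = bland_altman(np.array([10.0, 20.0, 30.0]),
                           np.array([10.2, 20.0, 30.0]))
        expected = 100.0 * (0.2 / np.sqrt(2.0)) / 10.1
        assert res.per_subject_cov[0] == pytest.approx(expected, abs=5e-4)

    def test_loa_symmetric_about_bias(self, rng):
        m1 = rng.normal(10, 1, 12)
        m2 = m1 + rng.normal(0, 0.3, 12)
        res = bland_altman(m1, m2)
        assert (res.loa_upper - res.bias) == pytest.approx(
            res.bias - res.loa_lower, rel=1e-9)

    def test_multiplicative_rescan_simulation(self):
        """2% multiplicative noise, n=7: mean CoV lands between 1 and 3
        percent and the bias stays non-significant in most seeds."""
        covs, bias_ps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m1 = rng.normal(10, 1, 7)
            m2 = m1 * (1 + rng.normal(0, 0.02, 7))
            res = bland_altman(m1, m2)
            covs.append(res.within_subject_cov)
            bias_ps.append(res.p_bias)
        assert 1.0 < np.mean(covs) < 3.0
        assert np.mean(np.array(bias_ps) > 0.05) >= 0.9


class TestShapiroWilk:
    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)

    def test_normal_sample_not_rejected(self, rng):
        w, p = shapiro_wilk(rng.normal(size=50))
        assert p > 0.05

    def test_exponential_sample_rejected(self, rng):
        w, p = shapiro_wilk(rng.exponential(size=100))
        assert p < 0.01


class TestCompareGroups:
    def _table(self, rng, delta=3.0):
        rows = []
        structures = [f"s{k}" for k in range(3)]
        for g, shift in (("control", delta), ("cuprizone", 0.0)):
            for i in range(7):
                for s in structures:
                    rows.append(dict(animal_id=f"{g}{i}", group=g,
                                     structure=s, measure="mpf_percent",
                                     value=rng.normal(10 + shift, 1.0)))
        return pd.DataFrame(rows)

    def test_separated_groups_detected(self, rng):
        gc = compare_groups(self._table(rng))
        assert gc.manova_p < 0.001
        assert 0 < gc.wilks_lambda < 1
        for name, r in gc.per_structure.items():
            assert r["p"] < 0.01
            assert r["d_ci"][0] <= r["d"] <= r["d_ci"][1]
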