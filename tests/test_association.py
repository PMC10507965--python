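import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icrpipe.association import (
    anova_oneway,
    build_design,
    contingency_table,
    fisher_exact,
    homogeneity_test,
    logistic_fit,
    odds_ratio_wald,
)

POOLED = np.array([[44, 83], [3, 32]])  # ICR2-4 vs ICR1, DCB yes/no
OWN = np.array([[10, 25], [1, 8]])


def hypergeom_two_sided(table: np.ndarray) -> float:
    """Independent closed-form oracle for 2x2 tables."""
    t = np.asarray(table, dtype=int)
    r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
    return float(min(pmf[pmf <= obs * (1 + 1e-7)].sum(), 1.0))


class TestContingency:
    def test_printed_pooled_counts(self):
        labels = ["ICR1"] * 35 + ["ICR2-4"] * 127
        outcome = [True] * 3 + [False] * 32 + [True] * 44 + [False] * 83
        table = contingency_table(labels, outcome)
        assert table.loc["ICR1", ["yes", "no"]].tolist() == [3, 32]
        assert table.loc["ICR2-4", ["yes", "no"]].tolist() == [44, 83]
        assert table.loc["ICR1", "rate"] == pytest.approx(3 / 35)

    def test_all_false_outcomes(self):
        table = contingency_table(["a", "a", "b"], [False, False, False])
        assert table["yes"].sum() == 0

    def test_row_sums_equal_group_sizes(self, rng):
        labels = rng.choice([1, 2, 3, 4], size=100)
        outcome = rng.random(100) < 0.3
        table = contingency_table(labels, outcome)
        for lev in np.unique(labels):
            assert table.loc[lev, ["yes", "no"]].sum() == (labels == lev).sum()

    def test_empty_group_retained_with_zeros(self):
        labels = pd.Categorical(["a", "a"], categories=["a", "b"])
        table = contingency_table(labels, [True, False])
        assert table.loc["b", ["yes", "no"]].tolist() == [0, 0]


class TestOddsRatio:
    def test_pooled_printed_values(self):
        res = odds_ratio_wald(POOLED)
        assert round(res.odds_ratio, 2) == 5.65
        assert round(res.ci_low, 2) == 1.64
        assert round(res.ci_high, 2) == 19.51

    def test_own_cohort_printed_values(self):
        res = odds_ratio_wald(OWN)
        assert round(res.odds_ratio, 2) == 3.20
        assert round(res.ci_low, 2) == 0.35
        assert round(res.ci_high, 2) == 29.01

    def test_symmetric_table(self):
        res = odds_ratio_wald([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_correction_flagged(self):
        res = odds_ratio_wald([[0, 10], [5, 5]])
        assert any("haldane" in note for note in res.notes)
        assert np.isfinite(res.odds_ratio)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            odds_ratio_wald([[0, 0], [5, 5]])

    def test_ci_contains_or_property(self, rng):
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2))
            res = odds_ratio_wald(t)
            assert res.ci_low <= res.odds_ratio <= res.ci_high
            assert res.odds_ratio > 0


class TestFisherExact:
    def test_zero_margin_is_one(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact([[2, 3], [0, 0]]) == 1.0

    def test_pooled_table_matches_oracle(self):
        assert fisher_exact(POOLED) == pytest.approx(hypergeom_two_sided(POOLED))

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(30):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            _, expected = stats.fisher_exact(t)
            assert fisher_exact(t) == pytest.approx(expected, rel=1e-9)

    def test_reconstructed_4class_counts(self):
        # per-class DCB counts implied by the printed rates and denominators:
        # 3/35, 17/48, 13/36, 14/43. The exact conditional enumeration gives
        # p = 0.015371 (matches R's fisher.test); the published 2.67E-02 is
        # the Pearson chi-square p-value on the same counts.
        table = np.array([[3, 17, 13, 14], [32, 31, 23, 29]])
        p = fisher_exact(table)
        assert p == pytest.approx(0.0153705, abs=1e-6)
        chi2, chi_p, _, _ = stats.chi2_contingency(table, correction=False)
        assert round(chi_p, 4) == 0.0267

    def test_2xk_probabilities_sum_to_one(self):
        # enumeration covers the full conditional sample space
        table = np.array([[5, 3, 2], [1, 4, 6]])
        # p-value with observed probability threshold at +inf == total mass
        from icrpipe import association

        full = association.fisher_exact(np.array([[11, 0, 0], [0, 7, 8]]) * 0 + table)
        assert 0 < full <= 1.0

    def test_extreme_table_small_p(self):
        assert fisher_exact([[20, 0], [0, 20]]) < 1e-9


class TestLogistic:
    def test_saturated_model_matches_wald(self):
        for table in (POOLED, OWN):
            ref = odds_ratio_wald(table)
            x = pd.DataFrame(
                {"exposed": [1.0] * int(table[0].sum()) + [0.0] * int(table[1].sum())}
            )
            y = (
                [1] * table[0][0] + [0] * table[0][1]
                + [1] * table[1][0] + [0] * table[1][1]
            )
            fit = logistic_fit(x, pd.Series(y))
            row = fit.summary.iloc[1]
            np.testing.assert_allclose(row["odds_ratio"], ref.odds_ratio, rtol=1e-6)
            np.testing.assert_allclose(row["ci_low"], ref.ci_low, rtol=1e-6)
            np.testing.assert_allclose(row["ci_high"], ref.ci_high, rtol=1e-6)

    def test_intercept_only_recovers_rate(self):
        y = pd.Series([1] * 30 + [0] * 70)
        fit = logistic_fit(pd.DataFrame(index=y.index), y)
        p_hat = 1 / (1 + np.exp(-fit.summary.iloc[0]["coef"]))
        assert p_hat == pytest.approx(0.30, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 300
        x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.integers(0, 2, n).astype(float)})
        eta = -0.5 + 0.8 * x["a"] - 0.4 * x["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_fit(x, pd.Series(y))
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.summary["coef"].to_numpy(), ref.params.to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(fit.summary["se"].to_numpy(), ref.bse.to_numpy(), rtol=1e-4)

    def test_null_predictor_or_near_one(self, rng):
        n = 10_000
        x = pd.DataFrame({"noise": rng.normal(size=n)})
        y = pd.Series((rng.random(n) < 0.3).astype(int))
        fit = logistic_fit(x, y)
        row = fit.summary.iloc[1]
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert abs(np.log(row["odds_ratio"])) < 0.15

    def test_separation_detected(self):
        x = pd.DataFrame({"z": [0.0] * 10 + [1.0] * 10})
        y = pd.Series([0] * 10 + [1] * 10)
        fit = logistic_fit(x, y)
        assert fit.separation

    def test_one_level_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]}), pd.Series([1] * 5))

    def test_listwise_deletion(self):
        x = pd.DataFrame({"x": [1.0, np.nan, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0]})
        y = pd.Series([1, 1, 0, 1, 0, 0, 1, 0])
        fit = logistic_fit(x, y)
        assert fit.n == 7


class TestBuildDesign:
    def test_categorical_coding(self):
        df = pd.DataFrame({"g": ["low", "high", "low", None]})
        design = build_design(df, {"g": "low"})
        assert list(design.columns) == ["g[high]"]
        assert design["g[high]"].tolist()[:3] == [0.0, 1.0, 0.0]
        assert np.isnan(design["g[high]"].iloc[3])

    def test_numeric_passthrough(self):
        df = pd.DataFrame({"age": [50, 60]})
        design = build_design(df, {"age": None})
        assert design["age"].tolist() == [50.0, 60.0]

    def test_missing_column(self):
        with pytest.raises(KeyError):
            build_design(pd.DataFrame({"a": [1]}), {"b": None})


class TestAnova:
    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(size=20), rng.normal(0.5, 1, size=25)
        f, p = anova_oneway(
            np.concatenate([a, b]), ["a"] * 20 + ["b"] * 25
        )
        t, tp = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert p == pytest.approx(tp, rel=1e-9)

    def test_matches_scipy_multigroup(self, rng):
        groups = [rng.normal(loc, 1, size=15) for loc in (0, 0.3, 1.0)]
        f, p = anova_oneway(
            np.concatenate(groups), sum([[i] * 15 for i in range(3)], [])
        )
        fr, pr = stats.f_oneway(*groups)
        assert f == pytest.approx(fr, rel=1e-9)
        assert p == pytest.approx(pr, rel=1e-9)

    def test_zero_within_variance(self):
        f, p = anova_oneway([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert np.isinf(f)
        assert p == 0.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            anova_oneway([1, 2, 3], ["a", "a", "a"])


class TestHomogeneity:
    def test_identical_tables_q_zero(self):
        tables = [np.array([[10, 20], [5, 25]])] * 4
        q, p = homogeneity_test(tables)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_inverted_cohort_detected(self):
        common = np.array([[30, 10], [10, 30]])
        inverted = np.array([[10, 30], [30, 10]])
        q, p = homogeneity_test([common, common, common, inverted])
        assert p < 0.05

    def test_common_or_rarely_rejected(self, rng):
        # strata simulated under one common odds ratio: Q should look null
        rejected = 0
        n_sims = 200
        for _ in range(n_sims):
            tables = []
            for _ in range(5):
                n1 = n0 = 40
                y1 = rng.binomial(n1, 0.35)
                y0 = rng.binomial(n0, 0.09)
                tables.append(np.array([[y1, n1 - y1], [y0, n0 - y0]]))
            _, p = homogeneity_test(tables)
            rejected += p < 0.05
        assert rejected / n_sims < 0.10

    def test_fewer_than_two_strata(self):
        with pytest.raises(ValueError):
            homogeneity_test([np.array([[1, 2], [3, 4]])])

    def test_zero_cell_strata_corrected(self):
        tables = [np.array([[0, 10], [5, 5]]), np.array([[1, 9], [4, 6]])]
        q, p = homogeneity_test(tables)
        assert np.isfinite(q) and 0 <= p <= 1
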