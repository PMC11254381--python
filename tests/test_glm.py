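import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from alphalat import (GeneratorConfig, draw_truth, fit_ols, model_search,
                      normality_check, one_sample_test, vif)
from alphalat.containers import STRUCTURES


def random_design(n, k, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    y = rng.standard_normal(n)
    return X, y


class TestFitOls:
    def test_exact_fit(self):
        x = np.arange(10.0)
        fit = fit_ols(x, 3.0 + 2.0 * x)
        np.testing.assert_allclose(fit.params, [3.0, 2.0], atol=1e-12)
        assert fit.rsquared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.resid, 0.0, atol=1e-12)

    def test_matches_normal_equations(self):
        X, y = random_design(8, 2, 0)
        fit = fit_ols(X, y)
        Xc = np.column_stack([np.ones(8), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)

    @pytest.mark.parametrize("n,k,seed", [(20, 3, 1), (33, 7, 2), (12, 1, 3)])
    def test_matches_statsmodels(self, n, k, seed):
        X, y = random_design(n, k, seed)
        fit = fit_ols(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.tvalues, ref.tvalues, rtol=1e-10)
        np.testing.assert_allclose(fit.pvalues, ref.pvalues, rtol=1e-8)
        assert fit.fvalue == pytest.approx(ref.fvalue, rel=1e-10)
        assert fit.f_pvalue == pytest.approx(ref.f_pvalue, rel=1e-8)
        assert fit.rsquared == pytest.approx(ref.rsquared, rel=1e-12)
        assert fit.rsquared_adj == pytest.approx(ref.rsquared_adj, rel=1e-12)
        assert fit.df_resid == n - k - 1
        # criteria count intercept + residual variance; same ranking as
        # statsmodels', offset by the constant for the variance parameter
        assert fit.aic == pytest.approx(ref.aic + 2.0, rel=1e-12)

    def test_t_equals_coef_over_se(self):
        X, y = random_design(25, 3, 4)
        fit = fit_ols(X, y)
        np.testing.assert_allclose(fit.tvalues, fit.params / fit.bse)

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = 2.0  # both columns constant -> collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            fit_ols(X, np.arange(10.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_ols(np.eye(3), np.arange(3.0))


@pytest.fixture(scope="module")
def lv_and_hlm():
    cfg = GeneratorConfig(n_subjects=40, seed=0)
    _, truth = draw_truth(cfg, np.random.default_rng(0))
    return truth.lv, truth.hlm


class TestModelSearch:
    def test_all_127_subsets_fitted(self, lv_and_hlm):
        lv, y = lv_and_hlm
        res = model_search(lv, y)
        assert len(res.entries) == 127
        assert len({e["subset"] for e in res.entries}) == 127

    def test_winner_minimizes_criterion(self, lv_and_hlm):
        lv, y = lv_and_hlm
        res = model_search(lv, y)
        best = min(e["aic"] for e in res.entries)
        win = next(e for e in res.entries if e["subset"] == res.winning_aic)
        assert win["aic"] == best
        best_bic = min(e["bic"] for e in res.entries)
        win_b = next(e for e in res.entries if e["subset"] == res.winning_bic)
        assert win_b["bic"] == best_bic

    def test_r2_nondecreasing_in_nested_subsets(self, lv_and_hlm):
        lv, y = lv_and_hlm
        res = model_search(lv, y)
        by_subset = {e["subset"]: e["r2"] for e in res.entries}
        full = by_subset[tuple(STRUCTURES)]
        for e in res.entries:
            assert e["r2"] <= full + 1e-12

    def test_zero_variance_regressor_rejected(self, lv_and_hlm):
        lv, y = lv_and_hlm
        bad = lv.copy()
        bad["Th"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            model_search(bad, y)

    def test_pure_noise_has_no_dominant_winner(self):
        # with no coupling, no single subset should win most replicates
        rng = np.random.default_rng(10)
        wins = {}
        for _ in range(100):
            X = pd.DataFrame(rng.standard_normal((33, 7)),
                             columns=STRUCTURES)
            y = rng.standard_normal(33)
            w = model_search(X, y).winning_aic
            wins[w] = wins.get(w, 0) + 1
        assert max(wins.values()) <= 50


class TestVif:
    def test_orthogonal_columns_give_unity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((64, 3))
        Q, _ = np.linalg.qr(X - X.mean(0))
        out = vif(pd.DataFrame(Q, columns=list("abc")))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-10)

    def test_duplicate_column_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        with pytest.raises(ValueError, match="collinear"):
            vif(df)

    def test_matches_statsmodels_on_random_design(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(7)
        base = rng.standard_normal((40, 3))
        X = np.column_stack([base, base @ [0.7, 0.2, 0.1]
                             + 0.3 * rng.standard_normal(40)])
        df = pd.DataFrame(X, columns=list("abcd"))
        ours = vif(df)
        Xc = sm.add_constant(X)
        for j, col in enumerate(df.columns):
            ref = variance_inflation_factor(Xc, j + 1)
            assert ours[col] == pytest.approx(ref, rel=1e-8)

    def test_near_collinear_matches_auxiliary_regression(self):
        rng = np.random.default_rng(2)
        x1 = rng.standard_normal(50)
        x2 = x1 + 0.01 * rng.standard_normal(50)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        out = vif(df)
        aux = fit_ols(df[["x1"]], df["x2"])
        assert out["x2"] == pytest.approx(1.0 / (1.0 - aux.rsquared), rel=1e-9)
        assert out["x2"] > 10


class TestOneSampleTest:
    def test_matches_printed_summary_arithmetic(self):
        # construct data with mean -0.0123 and sd 0.0121 at n=33: the
        # implied statistic is mean/(sd/sqrt(n)) ~= -5.84
        rng = np.random.default_rng(3)
        x = rng.standard_normal(33)
        x = (x - x.mean()) / x.std(ddof=1) * 0.0121 - 0.0123
        t, p = one_sample_test(x)
        assert t == pytest.approx(-0.0123 / (0.0121 / np.sqrt(33)), rel=1e-10)
        assert t == pytest.approx(-5.84, abs=0.005)
        assert p < 1e-5

    def test_symmetric_values_give_zero(self):
        t, p = one_sample_test([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert t == 0.0
        assert p == 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_sample_test([1.0, 1.0, 1.0, 1.0])


class TestNormalityCheck:
    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(33)
        w1, _ = normality_check(x)
        w2, _ = normality_check(3.7 * x + 11.0)
        assert w1 == pytest.approx(w2, rel=1e-10)

    def test_power_against_skewed_samples(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            normality_check(rng.exponential(size=33))[1] < 0.05
            for _ in range(200))
        assert rejections / 200 > 0.5

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
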