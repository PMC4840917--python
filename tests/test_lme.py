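"""Random-intercept REML engine: closed forms, oracles, cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vkproteome import (DegenerateDesignError, ModelSpec, RandomInterceptLM,
                        fit_random_intercept, fitted_r2, grid_reml_oracle,
                        wald_test)


def simulate_instance(rng, n_groups, per_group, sigma_u=0.6, sigma_e=0.5,
                      beta=(1.0, 0.5)):
    g = np.repeat(np.arange(n_groups), per_group)
    n = len(g)
    x = rng.normal(0, 1, n)
    y = beta[0] + beta[1] * x + rng.normal(0, sigma_u, n_groups)[g] \
        + rng.normal(0, sigma_e, n)
    return y, x, g


class TestClosedForms:
    def test_single_group_perfect_line_is_ols_limit(self):
        res = RandomInterceptLM([1.0, 2.0, 3.0], [0.0, 1.0, 2.0],
                                ["a", "a", "a"]).fit()
        assert res.beta1 == pytest.approx(1.0, abs=1e-12)
        assert res.sigma2_u == 0.0

    def test_single_group_equals_ols_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 25)
        y = 2.0 + 0.7 * x + rng.normal(0, 0.4, 25)
        res = RandomInterceptLM(y, x, np.zeros(25)).fit()
        X = np.column_stack([np.ones(25), x])
        beta_ols, rss = np.linalg.lstsq(X, y, rcond=None)[:2]
        s2 = rss[0] / 23.0
        se_ols = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.beta1 == pytest.approx(beta_ols[1], abs=1e-10)
        assert res.se_beta1 == pytest.approx(se_ols, abs=1e-10)
        assert res.sigma2_u == 0.0
        # p-value from the same z statistic
        z = beta_ols[1] / se_ols
        assert res.wald_pvalue() == pytest.approx(2 * stats.norm.sf(abs(z)),
                                                  abs=1e-12)

    def test_balanced_anova_variance_components(self):
        # intercept-only, balanced groups: REML equals the ANOVA estimators
        # sigma_e^2 = MSW, sigma_u^2 = (MSB - MSW) / m
        rng = np.random.default_rng(11)
        n_groups, m = 8, 6
        g = np.repeat(np.arange(n_groups), m)
        y = rng.normal(0, 1.2, n_groups)[g] + rng.normal(0, 0.8, n_groups * m)
        res = RandomInterceptLM(y, None, g).fit()
        means = y.reshape(n_groups, m).mean(axis=1)
        msw = ((y.reshape(n_groups, m) - means[:, None]) ** 2).sum() / \
            (n_groups * (m - 1))
        msb = m * ((means - means.mean()) ** 2).sum() / (n_groups - 1)
        assert res.sigma2_e == pytest.approx(msw, rel=1e-6)
        assert res.sigma2_u == pytest.approx((msb - msw) / m, rel=1e-6)


class TestOracleEquivalence:
    def test_profiled_reml_attains_grid_maximum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_groups = rng.integers(1, 7)
            per_group = rng.integers(3, 8)
            y, x, g = simulate_instance(rng, n_groups, per_group,
                                        sigma_u=rng.uniform(0, 1.5))
            res = RandomInterceptLM(y, x, g).fit()
            best, _, _ = grid_reml_oracle(y, x, g)
            assert res.loglik_reml >= best - 1e-6

    def test_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        y, x, g = simulate_instance(rng, 10, 8)
        mine = RandomInterceptLM(y, x, g).fit()
        md = sm.MixedLM(y, np.column_stack([np.ones(len(y)), x]),
                        groups=g).fit(reml=True)
        assert mine.beta1 == pytest.approx(md.params[1], abs=1e-6)
        assert mine.sigma2_e == pytest.approx(float(md.scale), rel=1e-5)
        assert mine.sigma2_u == pytest.approx(
            float(np.atleast_2d(md.cov_re)[0, 0]), rel=1e-4)
        assert mine.loglik_reml == pytest.approx(md.llf, abs=1e-5)
        # statsmodels reports Hessian-based SEs; the GLS plug-in SE used here
        # agrees to a few percent
        assert mine.se_beta1 == pytest.approx(md.bse_fe[1], rel=0.05)


class TestWald:
    def test_zero_slope_gives_p_one(self):
        fit = fit_random_intercept(ModelSpec(
            outcome=np.array([1.0, 2.0, 1.5, 2.5]),
            predictor=np.array([0.0, 1.0, 1.0, 0.0]),
            group=np.array([0, 0, 1, 1])))
        fit.beta1, fit.se_beta1 = 0.0, 0.3
        assert wald_test(fit) == pytest.approx(1.0)

    def test_z_1959964_gives_p_005(self):
        fit = fit_random_intercept(ModelSpec(
            outcome=np.array([1.0, 2.0, 1.5, 2.5]),
            predictor=np.array([0.0, 1.0, 1.0, 0.0]),
            group=np.array([0, 0, 1, 1])))
        fit.beta1, fit.se_beta1 = 1.959964, 1.0
        assert wald_test(fit) == pytest.approx(0.05, abs=1e-6)

    def test_symmetric_in_sign(self):
        rng = np.random.default_rng(9)
        y, x, g = simulate_instance(rng, 4, 6)
        p_pos = RandomInterceptLM(y, x, g).fit().wald_pvalue()
        p_neg = RandomInterceptLM(y, -x, g).fit().wald_pvalue()
        assert p_pos == pytest.approx(p_neg, abs=1e-12)

    def test_zero_se_rejected(self):
        res = RandomInterceptLM([1.0, 2.0, 3.0], [0.0, 1.0, 2.0],
                                ["a"] * 3).fit()
        with pytest.raises(ValueError, match="zero"):
            res.wald_pvalue()


class TestFittedR2:
    def test_perfect_fit_gives_one(self):
        res = RandomInterceptLM([1.0, 2.0, 3.0], [0.0, 1.0, 2.0],
                                ["a"] * 3).fit()
        assert res.r2() == pytest.approx(1.0)

    def test_constant_fitted_gives_zero(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 30)
        x = rng.normal(0, 1, 30)
        res = RandomInterceptLM(y, x, np.zeros(30)).fit()
        fit = res.fit
        fit.fitted_values = np.full(30, y.mean())
        assert fitted_r2(fit, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_outcome_rejected(self):
        res = RandomInterceptLM([1.0, 2.0, 3.0], [0.0, 1.0, 2.0],
                                ["a"] * 3).fit()
        with pytest.raises(ValueError, match="constant"):
            fitted_r2(res.fit, np.ones(3))

    def test_recovers_known_signal_fraction(self):
        # outcome variance split signal 0.3 / noise 0.7 at n = 474
        rng = np.random.default_rng(12)
        n, n_groups = 474, 72
        g = rng.integers(0, n_groups, n)
        x = rng.normal(0, 1.0, n)
        beta = np.sqrt(0.3)
        y = beta * x + rng.normal(0, np.sqrt(0.7), n)
        res = RandomInterceptLM(y, x, g).fit()
        assert res.r2() == pytest.approx(0.3, abs=0.06)


class TestInvariances:
    @settings(max_examples=15, deadline=None)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100),
           seed=st.integers(0, 1000))
    def test_equivariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        y, x, g = simulate_instance(rng, 5, 6)
        base = RandomInterceptLM(y, x, g).fit()
        shifted = RandomInterceptLM(y + shift, x, g).fit()
        scaled = RandomInterceptLM(y, x * scale, g).fit()
        assert shifted.beta1 == pytest.approx(base.beta1, rel=1e-6, abs=1e-9)
        assert shifted.beta0 == pytest.approx(base.beta0 + shift, rel=1e-6,
                                              abs=1e-6)
        assert scaled.beta1 == pytest.approx(base.beta1 / scale, rel=1e-6)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError, match="constant"):
            RandomInterceptLM([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], ["a"] * 3)
        with pytest.raises(DegenerateDesignError, match="3 observations"):
            RandomInterceptLM([1.0, 2.0], [0.0, 1.0], ["a", "a"])
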