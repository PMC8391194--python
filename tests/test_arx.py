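import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbdecide.arx import (
    ARXSpec,
    BayesianARX,
    MCMCConfig,
    PosteriorDraws,
    convergence_diagnostics,
    fit_arx,
    hpd_interval,
    one_step_oos_rmse,
    posterior_summary,
    predict_next,
)
from conftest import gen_ar

# Posterior moments of the p=0 two-covariate model on the shared seed-7
# dataset, computed by dense 3-D grid integration of the exact posterior
# (noise variance integrated analytically against its inverse-gamma prior).
GRID_MEANS = {"const": 0.923098, "x1": 0.423782, "x2": -1.258935}
GRID_SDS = {"const": 0.054742, "x1": 0.059791, "x2": 0.060529}
GRID_E_SIGMA2 = 0.223721


def manual_draws(names, values, n=200, n_chains=2, p=0, exog_names=()):
    """PosteriorDraws with every draw equal to the given parameter vector."""
    arr = np.tile(np.asarray(values, dtype=float), (n_chains, n, 1))
    spec = ARXSpec(p=p, exog_names=tuple(exog_names))
    return PosteriorDraws(list(names), arr, spec, MCMCConfig(2 * n, n, n_chains, 0))


class TestFitValidation:
    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient data"):
            BayesianARX(p=3, iterations=200, burn_in=100).fit(None, np.ones(3))

    def test_non_finite_values(self):
        y = np.ones(50)
        y[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            BayesianARX(p=1, iterations=200, burn_in=100).fit(None, y)

    def test_seed_determinism(self, regression_data):
        y, X = regression_data
        fits = [
            BayesianARX(p=0, iterations=500, burn_in=250, random_state=42).fit(X, y)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0].draws_.draws, fits[1].draws_.draws)


class TestPosteriorAgainstGridOracle:
    def test_moments_match_grid_integration(self, regression_data):
        """MCMC moments agree with dense-grid integration of the exact posterior."""
        y, X = regression_data
        est = BayesianARX(
            p=0, iterations=6000, burn_in=3000, n_chains=2,
            exog_names=("x1", "x2"), random_state=0,
        ).fit(X, y)
        s = est.summary_
        for name in GRID_MEANS:
            mc_se = s.loc[name, "sd"] / np.sqrt(est.ess_[name])
            assert abs(s.loc[name, "mean"] - GRID_MEANS[name]) < 3 * mc_se
            assert s.loc[name, "sd"] == pytest.approx(GRID_SDS[name], rel=0.05)
        assert s.loc["sigma2", "mean"] == pytest.approx(GRID_E_SIGMA2, rel=0.05)

    def test_parameter_recovery_arx1(self):
        """True ARX(1) parameters fall inside their 95% HPDs at n=500."""
        rng = np.random.default_rng(21)
        n = 500
        c = np.clip(rng.normal(0.1, 0.03, n), 0, 1)
        y = np.zeros(n)
        eps = rng.normal(0, 0.1, n)
        for t in range(1, n):
            y[t] = 30.0 - 5.0 * c[t] + 0.5 * y[t - 1] + eps[t]
        est = BayesianARX(
            p=1, iterations=3000, burn_in=1500, exog_names=("c",), random_state=1
        ).fit(c[:, None], y)
        s = est.summary_
        for name, true in [("const", 30.0), ("c", -5.0), ("phi1", 0.5),
                           ("sigma2", 0.01)]:
            assert s.loc[name, "hpd_lower"] <= true <= s.loc[name, "hpd_upper"]

    def test_support_constraints_hold(self):
        """AR draws stay in [-1, 1] and variance draws positive, even near a unit root."""
        y = gen_ar(300, (0.98,), 0.05, seed=9, level=0.0)
        est = BayesianARX(p=2, iterations=1500, burn_in=750, random_state=3).fit(None, y)
        pooled = est.draws_.pooled()
        assert np.all(np.abs(pooled[:, 1:3]) <= 1.0)
        assert np.all(pooled[:, -1] > 0)


class TestSummaries:
    def test_degenerate_draws(self):
        d = manual_draws(["const", "sigma2"], [5.0, 0.0])
        s = posterior_summary(d)
        assert s.loc["const", "mean"] == 5
        assert s.loc["const", "sd"] == 0
        assert (s.loc["const", "hpd_lower"], s.loc["const", "hpd_upper"]) == (5, 5)

    def test_hpd_of_normal_draws(self):
        x = np.random.default_rng(0).standard_normal(10**6)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_full_credibility_is_range(self):
        x = np.array([3.0, 1.0, 2.0])
        assert hpd_interval(x, 1.0) == (1.0, 3.0)

    @pytest.mark.parametrize("cred", [0.0, -0.5, 1.5])
    def test_invalid_credibility(self, cred):
        with pytest.raises(ValueError, match="cred"):
            hpd_interval(np.arange(10.0), cred)

    def test_too_few_draws(self):
        d = manual_draws(["const", "sigma2"], [1.0, 1.0], n=20)
        with pytest.raises(ValueError, match="100"):
            posterior_summary(d)

    @given(
        st.lists(st.floats(-100, 100), min_size=30, max_size=200),
        st.floats(0.3, 0.99),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_hpd_is_shortest_covering_window(self, values, cred):
        x = np.sort(np.asarray(values))
        lo, hi = hpd_interval(x, cred)
        m = int(np.ceil(cred * len(x)))
        assert np.sum((x >= lo) & (x <= hi)) >= m
        widths = x[m - 1 :] - x[: len(x) - m + 1]
        assert hi - lo <= widths.min() + 1e-9


class TestDiagnostics:
    def test_well_mixed_chains(self):
        rng = np.random.default_rng(5)
        arr = rng.standard_normal((2, 2000, 1))
        d = PosteriorDraws(["const"], arr, ARXSpec(p=0), MCMCConfig(100, 50, 2, 0))
        out = convergence_diagnostics(d)
        assert out.loc["const", "rhat"] == pytest.approx(1.0, abs=0.01)
        assert out.loc["const", "ess"] <= 2 * 2000 * 1.1

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(6)
        arr = np.stack([
            rng.standard_normal((1000, 1)),
            rng.standard_normal((1000, 1)) + 10.0,
        ])
        d = PosteriorDraws(["const"], arr, ARXSpec(p=0), MCMCConfig(100, 50, 2, 0))
        # classic between/within statistic as an independent formula check
        chains = arr[:, :, 0]
        w = chains.var(axis=1, ddof=1).mean()
        b = chains.shape[1] * chains.mean(axis=1).var(ddof=1)
        classic = np.sqrt(((chains.shape[1] - 1) / chains.shape[1] * w
                           + b / chains.shape[1]) / w)
        assert classic > 3
        assert convergence_diagnostics(d).loc["const", "rhat"] > 1.5

    def test_single_chain_is_error(self):
        arr = np.zeros((1, 500, 1))
        d = PosteriorDraws(["const"], arr, ARXSpec(p=0), MCMCConfig(100, 50, 1, 0))
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics(d)

    def test_constant_chains_warn(self):
        d = manual_draws(["const", "sigma2"], [1.0, 1.0])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = convergence_diagnostics(d)
        assert out["ess"].isna().all() or np.isnan(out.loc["const", "rhat"])


class TestPredictive:
    def test_degenerate_noise_gives_exact_linear_predictor(self):
        d = manual_draws(
            ["const", "c", "phi1", "sigma2"], [1.0, 2.0, 0.5, 0.0],
            p=1, exog_names=("c",),
        )
        out = predict_next(d, last_lags=[4.0], exog_scenario={"c": 3.0}, seed=0)
        np.testing.assert_allclose(out.values, 1.0 + 2.0 * 3.0 + 0.5 * 4.0)

    def test_predictive_mean_matches_posterior_mean_predictor(self, fast_mcmc):
        y = gen_ar(300, (0.6,), 0.2, seed=4)
        draws = fit_arx(y, None, ARXSpec(p=1), fast_mcmc(2))
        out = predict_next(draws, last_lags=y[-1:], seed=0)
        pooled = draws.pooled()
        analytic = pooled[:, 0].mean() + (pooled[:, 1] * y[-1]).mean()
        mc_se = out.values.std(ddof=1) / np.sqrt(len(out))
        assert out.mean == pytest.approx(analytic, abs=4 * mc_se)

    def test_wrong_lag_count_is_error(self):
        d = manual_draws(["const", "phi1", "phi2", "sigma2"],
                         [0.0, 0.5, 0.2, 1.0], p=2)
        with pytest.raises(ValueError, match="lag value"):
            predict_next(d, last_lags=[1.0], seed=0)

    def test_missing_scenario_covariate_is_error(self):
        d = manual_draws(["const", "c", "sigma2"], [0.0, 1.0, 1.0],
                         exog_names=("c",))
        with pytest.raises(ValueError, match="missing covariate"):
            predict_next(d, last_lags=[], exog_scenario={}, seed=0)


class TestOutOfSample:
    def test_noise_free_series_has_negligible_error(self):
        # deterministic AR(1) recursion: predictive mean should nail each step
        n = 120
        y = np.zeros(n)
        for t in range(1, n):
            y[t] = 1.0 + 0.9 * y[t - 1]
        res = one_step_oos_rmse(
            y, None, ARXSpec(p=1), MCMCConfig(1000, 500, 2, 0), holdout_steps=10
        )
        assert res.rmse < 0.01

    def test_rmse_approaches_noise_sd(self):
        """One-step error floor: RMSE -> sigma for a well-specified AR(1)."""
        sigma = 0.2
        y = gen_ar(1000, (0.6,), sigma, seed=11)
        res = one_step_oos_rmse(
            y, None, ARXSpec(p=1), MCMCConfig(2000, 1000, 2, 3), holdout_steps=100
        )
        assert res.rmse == pytest.approx(sigma, rel=0.20)
        assert res.rmse_pct == pytest.approx(100 * res.rmse / np.mean(res.actuals))

    def test_holdout_longer_than_series_is_error(self):
        with pytest.raises(ValueError, match="holdout"):
            one_step_oos_rmse(np.ones(20), None, ARXSpec(p=1),
                              MCMCConfig(200, 100, 2, 0), holdout_steps=25)
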