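"""Bayesian autoregressive regression with exogenous covariates (ARX).

The shared engine behind both the weekly employment model

    E_t = a0 + a1*c_t + a2*d_t + phi_1 E_{t-1} + ... + phi_p E_{t-p} + eps_t

and the daily fatality-rate model

    w_t = g0 + g1*c_t + phi_1 w_{t-1} + ... + phi_m w_{t-m} + eps_t

with eps_t ~ Normal(0, sigma^2).  Priors are deliberately diffuse:
Normal(0, 100) on the intercept and exogenous coefficients, Uniform[-1, 1]
on each autoregressive coefficient (the single-lag stationarity region,
applied per-coefficient for higher orders), and InverseGamma(0.01, 0.01)
on sigma^2.

Sampling is a two-block Gibbs scheme with exact full-conditional draws:
the whole coefficient vector given sigma^2 is multivariate normal truncated
to the AR box, sampled exactly by rejection from the untruncated normal
(with a coordinate-wise truncated-normal sweep as fallback when the
boundary binds), and sigma^2 given the coefficients is conjugate
inverse-gamma.  The likelihood conditions on the first p observations.
All per-iteration updates run on precomputed Gram matrices, so cost is
independent of the series length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ARXSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "PredictiveDraws",
    "BayesianARX",
    "fit_arx",
    "posterior_summary",
    "convergence_diagnostics",
    "predict_next",
    "one_step_oos_rmse",
    "hpd_interval",
]

RHAT_THRESHOLD = 1.05


@dataclass
class ARXSpec:
    """Model specification: lag order, covariate labels, prior hyperparameters."""

    p: int = 1
    exog_names: tuple[str, ...] = ()
    coef_prior_var: float = 100.0
    ar_bound: float = 1.0
    sigma2_shape: float = 0.01
    sigma2_scale: float = 0.01
    fix_sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("lag order p must be non-negative")
        if self.coef_prior_var <= 0 or self.sigma2_shape <= 0 or self.sigma2_scale <= 0:
            raise ValueError("prior variance hyperparameters must be positive")

    @property
    def param_names(self) -> list[str]:
        return (
            ["const"]
            + list(self.exog_names)
            + [f"phi{i}" for i in range(1, self.p + 1)]
            + ["sigma2"]
        )


@dataclass
class MCMCConfig:
    """Chain settings.  Defaults follow common practice for this model class:
    20,000 iterations per chain, the first 10,000 discarded, two chains."""

    iterations: int = 20_000
    burn_in: int = 10_000
    n_chains: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained post-burn-in MCMC samples, shape (n_chains, n_kept, n_params)."""

    names: list[str]
    draws: np.ndarray
    spec: ARXSpec
    mcmc: MCMCConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def param(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_kept)."""
        return self.draws[:, :, self.names.index(name)]

    def pooled(self) -> np.ndarray:
        """All chains stacked, shape (n_chains * n_kept, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.names)
            df.insert(0, "iteration", np.arange(self.n_kept))
            df.insert(0, "chain", c)
            rows.append(df.melt(id_vars=["chain", "iteration"],
                                var_name="parameter", value_name="value"))
        return pd.concat(rows, ignore_index=True)


@dataclass
class PredictiveDraws:
    """One-step-ahead predictive samples (one per retained posterior draw)."""

    values: np.ndarray
    exog_scenario: dict
    lags_used: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


def _design(y: np.ndarray, exog: np.ndarray | None, p: int):
    """Conditional-likelihood design: response y[p:], columns
    [1, exog, y_{t-1}, ..., y_{t-p}]."""
    n = len(y)
    y_eff = y[p:]
    cols = [np.ones(n - p)]
    if exog is not None:
        for j in range(exog.shape[1]):
            cols.append(exog[p:, j])
    for i in range(1, p + 1):
        cols.append(y[p - i : n - i])
    return y_eff, np.column_stack(cols)


def _sample_truncnorm(rng, mean, sd, lo, hi):
    """One draw from Normal(mean, sd) truncated to [lo, hi] via inverse CDF."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if b - a < 1e-300:  # conditional mass numerically outside the support
        return lo if mean < lo else hi
    u = a + (b - a) * rng.random()
    return float(np.clip(mean + sd * ndtri(u), lo, hi))


def _run_chain(y_eff, D, k_b, p, spec: ARXSpec, n_iter, burn_in, rng):
    """Gibbs sampler for one chain on precomputed Gram matrices.

    The full conditional of the whole coefficient vector given sigma^2 is a
    multivariate normal truncated to the AR box [-b, b]^p.  We draw from it
    exactly by rejection from the untruncated normal (the posterior mass
    inside the box is near 1 away from the boundary); if the boundary binds,
    the iteration falls back to coordinate-wise truncated-normal draws,
    which are exact full conditionals as well.
    """
    d_tot = k_b + p
    G = D.T @ D                      # (d_tot, d_tot)
    Dy = D.T @ y_eff                 # (d_tot,)
    yy = float(y_eff @ y_eff)
    n_eff = len(y_eff)
    bound = spec.ar_bound

    # start from ridge-regularised least squares, AR part clipped inside the prior
    theta = np.linalg.solve(G + 1e-6 * np.eye(d_tot), Dy)
    theta[k_b:] = np.clip(theta[k_b:], -0.99 * bound, 0.99 * bound)
    resid_ss = max(yy - 2 * theta @ Dy + theta @ G @ theta, 1e-12)
    sigma2 = spec.fix_sigma2 if spec.fix_sigma2 is not None else resid_ss / max(n_eff - d_tot, 1)

    prior_prec_diag = np.zeros(d_tot)
    prior_prec_diag[:k_b] = 1.0 / spec.coef_prior_var   # flat (uniform) on AR coefs
    kept = np.empty((n_iter - burn_in, d_tot + 1))
    G_aa = G[k_b:, k_b:]
    max_tries = 50

    diag = np.diag_indices(d_tot)
    for it in range(n_iter):
        # --- coefficients: truncated-MVN full conditional ---
        prec = G / sigma2
        prec[diag] += prior_prec_diag
        cov = np.linalg.inv(prec)
        mean = cov @ (Dy / sigma2)
        A = np.linalg.cholesky(cov)
        accepted = False
        for _ in range(max_tries):
            cand = mean + A @ rng.standard_normal(d_tot)
            if p == 0 or np.all(np.abs(cand[k_b:]) <= bound):
                theta = cand
                accepted = True
                break
        if not accepted:
            # boundary binds: one sweep of exact coordinate-wise conditionals
            cond_var = sigma2  # noise variance enters each scalar conditional
            beta_prec = prec[:k_b, :k_b]
            rhs = (Dy[:k_b] - G[:k_b, k_b:] @ theta[k_b:]) / sigma2
            cov_b = np.linalg.inv(beta_prec)
            mb = cov_b @ rhs
            theta[:k_b] = mb + np.linalg.cholesky(cov_b) @ rng.standard_normal(k_b)
            phi = theta[k_b:]
            for i in range(p):
                gii = G_aa[i, i]
                if gii <= 0:
                    phi[i] = rng.uniform(-bound, bound)
                    continue
                partial = (Dy[k_b + i] - G[k_b + i, :k_b] @ theta[:k_b]
                           - (G_aa[i] @ phi - gii * phi[i]))
                _m = partial / gii
                _s = np.sqrt(cond_var / gii)
                phi[i] = _sample_truncnorm(rng, _m, _s, -bound, bound)

        # --- sigma^2: conjugate inverse-gamma ---
        if spec.fix_sigma2 is None:
            ss = max(yy - 2 * theta @ Dy + theta @ G @ theta, 1e-12)
            shape = spec.sigma2_shape + 0.5 * n_eff
            scale = spec.sigma2_scale + 0.5 * ss
            sigma2 = scale / rng.gamma(shape)

        if it >= burn_in:
            kept[it - burn_in, :d_tot] = theta
            kept[it - burn_in, d_tot] = sigma2
    return kept


class BayesianARX(RegressorMixin, BaseEstimator):
    """Bayesian ARX(p) regression estimator.

    Parameters
    ----------
    p : int
        Autoregressive lag order.
    coef_prior_var : float
        Prior variance of the Normal(0, .) prior on the intercept and
        exogenous coefficients.
    ar_bound : float
        Half-width of the uniform prior support for each AR coefficient.
    sigma2_shape, sigma2_scale : float
        Inverse-gamma hyperparameters for the noise variance.
    fix_sigma2 : float or None
        If given, the noise variance is held at this value (no sampling).
    iterations, burn_in, n_chains : int
        MCMC settings per chain.
    random_state : int or None
        Seed; identical seeds and inputs give bit-identical draws.

    Attributes
    ----------
    draws_ : PosteriorDraws
    summary_ : pandas.DataFrame with mean, sd and 95% HPD bounds per parameter
    rhat_, ess_ : pandas.Series of split-R-hat and bulk effective sample size
    """

    def __init__(
        self,
        p: int = 1,
        coef_prior_var: float = 100.0,
        ar_bound: float = 1.0,
        sigma2_shape: float = 0.01,
        sigma2_scale: float = 0.01,
        fix_sigma2: float | None = None,
        iterations: int = 20_000,
        burn_in: int = 10_000,
        n_chains: int = 2,
        exog_names: tuple | None = None,
        random_state: int | None = None,
    ):
        self.p = p
        self.coef_prior_var = coef_prior_var
        self.ar_bound = ar_bound
        self.sigma2_shape = sigma2_shape
        self.sigma2_scale = sigma2_scale
        self.fix_sigma2 = fix_sigma2
        self.iterations = iterations
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.exog_names = exog_names
        self.random_state = random_state

    def _spec(self, n_exog: int) -> ARXSpec:
        names = tuple(self.exog_names) if self.exog_names is not None else tuple(
            f"x{j}" for j in range(n_exog)
        )
        if len(names) != n_exog:
            raise ValueError("exog_names length does not match number of covariates")
        return ARXSpec(
            p=self.p,
            exog_names=names,
            coef_prior_var=self.coef_prior_var,
            ar_bound=self.ar_bound,
            sigma2_shape=self.sigma2_shape,
            sigma2_scale=self.sigma2_scale,
            fix_sigma2=self.fix_sigma2,
        )

    def fit(self, X, y):
        """Sample the posterior given outcome ``y`` and exogenous matrix ``X``
        (may be None for a pure AR model)."""
        y = np.asarray(y, dtype=float).ravel()
        exog = None
        if X is not None:
            exog = np.asarray(X, dtype=float)
            if exog.ndim == 1:
                exog = exog[:, None]
            if len(exog) != len(y):
                raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(y)) or (exog is not None and not np.all(np.isfinite(exog))):
            raise ValueError("non-finite values in inputs")
        if len(y) < self.p + 10:
            raise ValueError(
                f"insufficient data: need at least p + 10 = {self.p + 10} "
                f"observations, got {len(y)}"
            )
        spec = self._spec(0 if exog is None else exog.shape[1])
        mcmc = MCMCConfig(self.iterations, self.burn_in, self.n_chains, self.random_state)

        y_eff, D = _design(y, exog, self.p)
        k_b = 1 + (0 if exog is None else exog.shape[1])
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_chains)
        chains = [
            _run_chain(y_eff, D, k_b, self.p, spec, self.iterations, self.burn_in,
                       np.random.default_rng(s))
            for s in seeds
        ]
        draws = PosteriorDraws(spec.param_names, np.stack(chains), spec, mcmc)

        self.n_features_in_ = 0 if exog is None else exog.shape[1]
        self._y_tail = y[len(y) - self.p :] if self.p else np.empty(0)
        self._y = y
        self._exog = exog
        self.draws_ = draws
        if self.n_chains >= 2:
            diag_names = [n for n in draws.names
                          if not (n == "sigma2" and self.fix_sigma2 is not None)]
            diag = convergence_diagnostics(draws, names=diag_names)
            self.rhat_ = diag["rhat"]
            self.ess_ = diag["ess"]
            bad = diag.index[diag["rhat"] > RHAT_THRESHOLD].tolist()
            if bad:
                msg = f"split-R-hat above {RHAT_THRESHOLD} for {bad}"
                draws.warnings.append(msg)
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
        self.summary_ = posterior_summary(draws)
        return self

    def sample_predictive(self, exog_scenario=None, last_lags=None,
                          random_state: int | None = None) -> PredictiveDraws:
        """One-step-ahead predictive draws for a covariate scenario.

        ``last_lags`` are the most recent ``p`` outcome values in time order
        (``last_lags[-1]`` is the current value); defaults to the tail of
        the training series.
        """
        if not hasattr(self, "draws_"):
            raise AttributeError("estimator is not fitted")
        if last_lags is None:
            last_lags = self._y_tail
        return predict_next(self.draws_, last_lags, exog_scenario, seed=random_state)

    def predict(self, X, last_lags=None):
        """Posterior-mean one-step-ahead prediction for each covariate row,
        each row treated as an independent scenario from the training tail."""
        if not hasattr(self, "draws_"):
            raise AttributeError("estimator is not fitted")
        if X is None:
            X = np.empty((1, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None] if self.n_features_in_ == 1 else X[None, :]
        theta = self.draws_.pooled().mean(axis=0)
        out = np.empty(len(X))
        lags = self._y_tail if last_lags is None else np.asarray(last_lags, float)
        for i, row in enumerate(X):
            out[i] = _linear_predictor(theta, row, lags, self.p, self.n_features_in_)
        return out


def _linear_predictor(theta, exog_row, lags, p, k):
    mu = theta[0]
    if k:
        mu += float(np.dot(theta[1 : 1 + k], exog_row))
    for i in range(1, p + 1):       # phi_i multiplies the value i steps back
        mu += theta[k + i] * lags[-i]
    return mu


def fit_arx(y, exog, spec: ARXSpec, mcmc: MCMCConfig | None = None) -> PosteriorDraws:
    """Functional wrapper over :class:`BayesianARX`."""
    mcmc = mcmc or MCMCConfig()
    est = BayesianARX(
        p=spec.p,
        coef_prior_var=spec.coef_prior_var,
        ar_bound=spec.ar_bound,
        sigma2_shape=spec.sigma2_shape,
        sigma2_scale=spec.sigma2_scale,
        fix_sigma2=spec.fix_sigma2,
        iterations=mcmc.iterations,
        burn_in=mcmc.burn_in,
        n_chains=mcmc.n_chains,
        exog_names=spec.exog_names or None,
        random_state=mcmc.seed,
    )
    est.fit(exog, y)
    return est.draws_


def hpd_interval(samples: np.ndarray, cred: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``cred`` mass of the samples."""
    if not 0 < cred <= 1:
        raise ValueError("cred must lie in (0, 1]")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    m = int(np.ceil(cred * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def posterior_summary(draws: PosteriorDraws, cred: float = 0.95) -> pd.DataFrame:
    """Mean, SD and HPD bounds per parameter over pooled chains."""
    if not 0 < cred <= 1:
        raise ValueError("cred must lie in (0, 1]")
    pooled = draws.pooled()
    if pooled.shape[0] < 100:
        raise ValueError("need at least 100 retained draws for summaries")
    rows = {}
    for j, name in enumerate(draws.names):
        x = pooled[:, j]
        lo, hi = hpd_interval(x, cred)
        rows[name] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "hpd_lower": lo,
            "hpd_upper": hi,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def convergence_diagnostics(draws: PosteriorDraws, names=None) -> pd.DataFrame:
    """Split-R-hat and bulk effective sample size per parameter (via arviz)."""
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError(
            "convergence diagnostics need >= 2 chains; rerun with n_chains >= 2 "
            "or split a single chain manually"
        )
    if names is None:
        names = draws.names
    data = {name: draws.param(name) for name in names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(data)
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    out = pd.DataFrame(
        {
            "rhat": [float(rhat[n].values) for n in names],
            "ess": [float(ess[n].values) for n in names],
        },
        index=list(names),
    )
    if out["rhat"].isna().any() or out["ess"].isna().any():
        warnings.warn(
            "degenerate (constant) chains: diagnostics undefined for some parameters",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def predict_next(
    draws: PosteriorDraws,
    last_lags,
    exog_scenario=None,
    seed: int | None = None,
) -> PredictiveDraws:
    """One-step-ahead predictive simulation.

    Each retained posterior draw contributes one predictive sample:
    the linear predictor under that draw plus Normal(0, sigma2_draw) noise.
    ``last_lags`` holds the most recent p outcome values in time order.
    """
    spec = draws.spec
    p, k = spec.p, len(spec.exog_names)
    last_lags = np.asarray(last_lags, dtype=float).ravel()
    if len(last_lags) != p:
        raise ValueError(f"need exactly {p} lag value(s), got {len(last_lags)}")
    if exog_scenario is None:
        exog_scenario = {}
    if isinstance(exog_scenario, dict):
        missing = [n for n in spec.exog_names if n not in exog_scenario]
        if missing:
            raise ValueError(f"scenario missing covariate(s) {missing}")
        exog_row = np.array([float(exog_scenario[n]) for n in spec.exog_names])
        scen = dict(exog_scenario)
    else:
        exog_row = np.asarray(exog_scenario, dtype=float).ravel()
        if len(exog_row) != k:
            raise ValueError(f"scenario needs {k} covariate value(s)")
        scen = dict(zip(spec.exog_names, exog_row))

    pooled = draws.pooled()
    mu = pooled[:, 0].copy()
    if k:
        mu += pooled[:, 1 : 1 + k] @ exog_row
    for i in range(1, p + 1):
        mu += pooled[:, k + i] * last_lags[-i]
    sigma = np.sqrt(pooled[:, -1])
    rng = np.random.default_rng(seed)
    values = mu + sigma * rng.standard_normal(len(mu))
    return PredictiveDraws(values=values, exog_scenario=scen, lags_used=last_lags)


@dataclass
class OOSResult:
    rmse: float            # native outcome scale
    rmse_pct: float        # as percentage of the holdout mean
    predictions: np.ndarray
    actuals: np.ndarray


def one_step_oos_rmse(
    y,
    exog,
    spec: ARXSpec,
    mcmc: MCMCConfig | None = None,
    holdout_steps: int = 1,
    refit: bool = False,
) -> OOSResult:
    """One-step-ahead out-of-sample RMSE of predictive means over a holdout.

    The model is fit on the first ``n - holdout_steps`` observations; each
    holdout step is predicted one step ahead conditioning on the *observed*
    lags (set ``refit=True`` to re-estimate the posterior each step).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if holdout_steps < 1:
        raise ValueError("holdout_steps must be >= 1")
    if holdout_steps >= n:
        raise ValueError("holdout longer than the series")
    n_train = n - holdout_steps
    if n_train < spec.p + 10:
        raise ValueError("training window too short for the requested lag order")
    exog_arr = None if exog is None else np.asarray(exog, dtype=float)
    if exog_arr is not None and exog_arr.ndim == 1:
        exog_arr = exog_arr[:, None]

    mcmc = mcmc or MCMCConfig()
    preds = np.empty(holdout_steps)
    draws = fit_arx(y[:n_train], None if exog_arr is None else exog_arr[:n_train], spec, mcmc)
    for j in range(holdout_steps):
        t = n_train + j
        if refit and j > 0:
            draws = fit_arx(y[:t], None if exog_arr is None else exog_arr[:t], spec, mcmc)
        lags = y[t - spec.p : t] if spec.p else np.empty(0)
        row = {} if exog_arr is None else dict(zip(spec.exog_names, exog_arr[t]))
        pd_draws = predict_next(draws, lags, row, seed=mcmc.seed)
        preds[j] = pd_draws.mean
    actual = y[n_train:]
    rmse = float(np.sqrt(np.mean((preds - actual) ** 2)))
    denom = float(np.mean(actual))
    rmse_pct = float("nan") if denom == 0 else 100.0 * rmse / abs(denom)
    return OOSResult(rmse=rmse, rmse_pct=rmse_pct, predictions=preds, actuals=actual)
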