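"""Lag-order selection by posterior model probability.

Candidate ARX(p) models for p = 1..p_max are scored by their marginal
likelihood (evidence) and combined under a uniform model prior:

    P(p | y)  proportional to  m_p(y)

so the reported probabilities are exp(log-evidence) renormalised over the
candidates.  Every candidate is scored on the common window obtained by
dropping the first p_max observations, so evidence values are comparable.

The evidence is estimated by the Laplace–Metropolis method: the posterior
mean and covariance of the retained MCMC draws (with sigma^2 mapped to the
log scale so the Gaussian approximation is applied on an unconstrained
coordinate) plug into the Laplace approximation

    log m(y) ~= d/2 log(2 pi) + 1/2 log|S| + log L(theta*) + log pi(theta*)

evaluated at the posterior mean theta*, with S the posterior covariance of
the draws.  The estimator is deterministic given the draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .arx import ARXSpec, MCMCConfig, BayesianARX, PosteriorDraws, _design

__all__ = [
    "log_marginal_likelihood",
    "evidence_from_draws",
    "select_lag",
    "ModelComparison",
    "ARXOrderSelector",
]


def _log_likelihood(theta, sigma2, y_eff, D):
    resid = y_eff - D @ theta
    n = len(y_eff)
    return -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * resid @ resid / sigma2


def _log_prior(theta, log_sigma2, spec: ARXSpec, k_b: int):
    """Log prior density at (theta, log sigma^2), Jacobian included.

    Normal(0, v) on the k_b non-AR coefficients, Uniform[-b, b] per AR
    coefficient, InverseGamma(a, s) on sigma^2 transformed to the log scale
    (density times |d sigma^2 / d log sigma^2| = sigma^2).
    """
    v = spec.coef_prior_var
    beta = theta[:k_b]
    lp = -0.5 * k_b * np.log(2 * np.pi * v) - 0.5 * beta @ beta / v
    phi = theta[k_b:]
    b = spec.ar_bound
    if np.any(np.abs(phi) > b):
        return -np.inf
    lp += -len(phi) * np.log(2 * b)
    if spec.fix_sigma2 is None:
        from scipy.stats import invgamma

        sigma2 = np.exp(log_sigma2)
        lp += invgamma.logpdf(sigma2, spec.sigma2_shape, scale=spec.sigma2_scale)
        lp += log_sigma2  # Jacobian of sigma^2 -> log sigma^2
    return lp


def evidence_from_draws(draws: PosteriorDraws, y, exog) -> float:
    """Laplace–Metropolis log evidence from fitted posterior draws."""
    spec = draws.spec
    y = np.asarray(y, dtype=float).ravel()
    exog_arr = None if exog is None else np.atleast_2d(np.asarray(exog, dtype=float))
    if exog_arr is not None and exog_arr.shape[0] != len(y):
        exog_arr = exog_arr.T
    y_eff, D = _design(y, exog_arr, spec.p)
    k_b = 1 + len(spec.exog_names)

    pooled = draws.pooled()
    theta_draws = pooled[:, :-1]
    if spec.fix_sigma2 is None:
        z = np.column_stack([theta_draws, np.log(pooled[:, -1])])
    else:
        z = theta_draws
    z_bar = z.mean(axis=0)
    S = np.cov(z, rowvar=False)
    S = np.atleast_2d(S)
    d = z.shape[1]

    theta_star = z_bar[: theta_draws.shape[1]]
    log_sigma2_star = z_bar[-1] if spec.fix_sigma2 is None else np.log(spec.fix_sigma2)
    sigma2_star = np.exp(log_sigma2_star) if spec.fix_sigma2 is None else spec.fix_sigma2
    # posterior mean of an AR coefficient can only reach the boundary in
    # degenerate cases; nudge inside so the prior density is finite
    theta_star = theta_star.copy()
    theta_star[k_b:] = np.clip(theta_star[k_b:], -spec.ar_bound + 1e-12,
                               spec.ar_bound - 1e-12)

    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("posterior covariance of draws is not positive definite")
    ll = _log_likelihood(theta_star, sigma2_star, y_eff, D)
    lp = _log_prior(theta_star, log_sigma2_star, spec, k_b)
    return float(0.5 * d * np.log(2 * np.pi) + 0.5 * logdet + ll + lp)


def log_marginal_likelihood(
    y, exog, spec: ARXSpec, mcmc: MCMCConfig | None = None
) -> float:
    """Fit the ARX model and return its Laplace–Metropolis log evidence."""
    from .arx import fit_arx

    mcmc = mcmc or MCMCConfig()
    draws = fit_arx(y, exog, spec, mcmc)
    return evidence_from_draws(draws, y, exog)


class ModelComparison:
    """Evidence and posterior model probability per candidate lag order."""

    def __init__(self, lags, log_evidence):
        self.lags = list(lags)
        self.log_evidence = np.asarray(log_evidence, dtype=float)
        shifted = self.log_evidence - self.log_evidence.max()
        w = np.exp(shifted)
        self.posterior_prob = w / w.sum()

    @property
    def best_lag(self) -> int:
        return self.lags[int(np.argmax(self.posterior_prob))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "log_evidence": self.log_evidence,
                "posterior_prob": np.round(self.posterior_prob, 4),
            }
        )


class ARXOrderSelector(BaseEstimator):
    """Select the ARX lag order by posterior model probability.

    Fits :class:`~nbdecide.arx.BayesianARX` for each p in 1..p_max on the
    common window (first p_max observations dropped for every candidate)
    and normalises the Laplace–Metropolis evidences under a uniform prior
    over candidates.

    Attributes
    ----------
    comparison_ : ModelComparison
    best_p_ : int
    posterior_prob_ : ndarray aligned with candidate lags 1..p_max
    """

    def __init__(
        self,
        p_max: int = 7,
        iterations: int = 20_000,
        burn_in: int = 10_000,
        n_chains: int = 2,
        exog_names: tuple | None = None,
        random_state: int | None = None,
    ):
        self.p_max = p_max
        self.iterations = iterations
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.exog_names = exog_names
        self.random_state = random_state

    def fit(self, X, y):
        if self.p_max < 1:
            raise ValueError("p_max must be >= 1")
        y = np.asarray(y, dtype=float).ravel()
        exog = None if X is None else np.asarray(X, dtype=float)
        if exog is not None and exog.ndim == 1:
            exog = exog[:, None]
        if len(y) < self.p_max + 10:
            raise ValueError("series too short for the largest candidate")

        log_ev = []
        lags = list(range(1, self.p_max + 1))
        for p in lags:
            # common window: drop the first p_max points for every candidate,
            # leaving p own-lags available from the dropped region
            offset = self.p_max - p
            y_c = y[offset:]
            exog_c = None if exog is None else exog[offset:]
            spec = ARXSpec(
                p=p,
                exog_names=tuple(self.exog_names) if self.exog_names else
                (() if exog is None else tuple(f"x{j}" for j in range(exog.shape[1]))),
            )
            mcmc = MCMCConfig(self.iterations, self.burn_in, self.n_chains,
                              self.random_state)
            from .arx import fit_arx

            draws = fit_arx(y_c, exog_c, spec, mcmc)
            log_ev.append(evidence_from_draws(draws, y_c, exog_c))
        self.comparison_ = ModelComparison(lags, log_ev)
        self.best_p_ = self.comparison_.best_lag
        self.posterior_prob_ = self.comparison_.posterior_prob
        self.log_evidence_ = self.comparison_.log_evidence
        return self


def select_lag(
    y,
    exog=None,
    p_max: int = 7,
    mcmc: MCMCConfig | None = None,
    exog_names: tuple | None = None,
) -> ModelComparison:
    """Functional wrapper over :class:`ARXOrderSelector`."""
    mcmc = mcmc or MCMCConfig()
    sel = ARXOrderSelector(
        p_max=p_max,
        iterations=mcmc.iterations,
        burn_in=mcmc.burn_in,
        n_chains=mcmc.n_chains,
        exog_names=exog_names,
        random_state=mcmc.seed,
    )
    sel.fit(exog, y)
    return sel.comparison_
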