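import numpy as np
import pytest

from nbdecide.arx import MCMCConfig


@pytest.fixture
def fast_mcmc():
    """Reduced-size MCMC settings for test fits (factory keyed by seed)."""

    def make(seed=0, iterations=2000, burn_in=1000, n_chains=2):
        return MCMCConfig(iterations, burn_in, n_chains, seed)

    return make


@pytest.fixture(scope="session")
def regression_data():
    """Deterministic p=0 regression dataset shared with the grid oracle."""
    rng = np.random.default_rng(7)
    n = 80
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 1.0 + 0.5 * x1 - 1.2 * x2 + rng.normal(0, 0.5, n)
    return y, np.column_stack([x1, x2])


def gen_ar(n, phi, sigma, seed, level=10.0, burn=50):
    """Plain AR series with a level shift, for sampler and selection tests."""
    p = len(phi)
    rng = np.random.default_rng(seed)
    y = np.zeros(n + burn)
    eps = rng.normal(0, sigma, n + burn)
    for t in range(p, n + burn):
        y[t] = sum(phi[i] * y[t - 1 - i] for i in range(p)) + eps[t]
    return y[burn:] + level
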