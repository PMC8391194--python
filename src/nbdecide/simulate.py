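"""Synthetic weekly employment and daily epidemic panels with known truth.

The generators realise exactly the statistical structure the two ARX
models assume, so every pipeline stage can be exercised end to end with
ground truth attached:

* the weekly employment panel follows the ARX recursion
  ``E_t = a0 + a1 c_t + a2 d_t + sum_i phi_i E_{t-i} + eps_t`` with a
  recession window and an open-ended pandemic window driving the regime
  dummy, and an infection-rate path that is zero before pandemic onset;
* the daily epidemic panel back-constructs cumulative counts from a
  simulated lagged-fatality-rate process
  ``w_t = g0 + g1 c_t + sum_i phi_i w_{t-i} + eps_t`` so that
  ``compute_death_rate`` recovers the simulated process up to count
  rounding.  Deaths are derived from rates rather than from a mechanistic
  epidemic, because the fatality model is a statistical model on rates.

Default parameter values mirror the magnitudes of the Florida analysis:
employment on the 0-100 percent scale with a long-run level near 60%,
week-level noise sd ~0.15 percentage points, a strongly negative
infection-rate coefficient, and a persistent daily fatality-rate process
around 3-4% driven by a test-positivity path that ramps up after onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import DailyEpidemicSeries, WeeklySeries
from .datasets import fixture_florida_tables  # noqa: F401  (re-export)

__all__ = [
    "EmploymentGenConfig",
    "EpidemicGenConfig",
    "gen_employment_panel",
    "gen_epidemic_panel",
    "fixture_florida_tables",
]


def _ramp(n: int, lo: float, hi: float) -> np.ndarray:
    """Smooth logistic ramp from lo to hi over n points."""
    if n <= 0:
        return np.empty(0)
    x = np.linspace(-4, 4, n)
    return lo + (hi - lo) / (1 + np.exp(-x))


@dataclass
class EmploymentGenConfig:
    """Ground-truth configuration for the weekly employment generator.

    Weeks start Monday.  The dummy is 1 inside the recession window and
    from pandemic onset onward; the infection-rate path is zero before
    onset and follows ``infection_path`` (default: logistic ramp to
    ``infection_peak``) afterwards.
    """

    alpha0: float = 3.0
    alpha1: float = -5.67          # percent employment per unit infection fraction
    alpha2: float = -0.05          # regime-shift level effect
    phi: tuple[float, ...] = (0.35, 0.95, -0.05, -0.30)
    sigma: float = 0.155
    n_weeks: int = 696
    start: str = "2007-01-01"
    recession: tuple[str, str] = ("2007-12-03", "2009-06-29")
    onset: str | None = "2020-03-02"   # None: 95% of the way through the series
    infection_peak: float = 0.12
    infection_path: np.ndarray | None = None
    initial: tuple[float, ...] | None = None   # pre-sample lag values (time order)
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(abs(f) > 1 for f in self.phi):
            raise ValueError("each AR coefficient must lie in [-1, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.infection_peak <= 1:
            raise ValueError("infection_peak must lie in [0, 1]")


def gen_employment_panel(cfg: EmploymentGenConfig) -> WeeklySeries:
    """Simulate a weekly employment panel; ground truth rides on ``.truth``."""
    p = len(cfg.phi)
    dates = pd.date_range(cfg.start, periods=cfg.n_weeks, freq="7D")
    if cfg.onset is None:
        onset = dates[int(0.95 * (cfg.n_weeks - 1))]
    else:
        onset = pd.Timestamp(cfg.onset)
        if not dates[0] <= onset <= dates[-1]:
            raise ValueError("pandemic onset must fall inside the series")
    rec_lo, rec_hi = (pd.Timestamp(d) for d in cfg.recession)
    dummy = (((dates >= rec_lo) & (dates <= rec_hi)) | (dates >= onset)).astype(int)

    c = np.zeros(cfg.n_weeks)
    post = np.flatnonzero(dates >= onset)
    if cfg.infection_path is not None:
        path = np.asarray(cfg.infection_path, dtype=float)
        if len(path) != len(post):
            raise ValueError("infection_path length must match post-onset weeks")
        c[post] = path
    else:
        c[post] = _ramp(len(post), min(0.005, cfg.infection_peak), cfg.infection_peak)

    drift = np.sum(cfg.phi)
    if abs(drift) >= 1:
        warnings.warn(
            "AR coefficients sum to a modulus >= 1: the recursion may drift "
            "off the 0-100 employment range",
            RuntimeWarning,
            stacklevel=2,
        )
    level = cfg.alpha0 / (1 - drift) if abs(drift) < 1 else 60.0
    init = np.asarray(cfg.initial if cfg.initial is not None else [level] * p, float)
    if len(init) != p:
        raise ValueError("need one initial value per lag")

    rng = np.random.default_rng(cfg.seed)
    eps = rng.normal(0.0, cfg.sigma, cfg.n_weeks)
    buf = np.concatenate([init, np.zeros(cfg.n_weeks)])
    for t in range(cfg.n_weeks):
        val = cfg.alpha0 + cfg.alpha1 * c[t] + cfg.alpha2 * dummy[t] + eps[t]
        for i, f in enumerate(cfg.phi, start=1):
            val += f * buf[p + t - i]
        buf[p + t] = val
    values = buf[p:]
    if np.any((values < 0) | (values > 100)):
        warnings.warn(
            "employment recursion left [0, 100]; clipping", RuntimeWarning, stacklevel=2
        )
        values = np.clip(values, 0.0, 100.0)

    truth = {
        "alpha0": cfg.alpha0,
        "alpha1": cfg.alpha1,
        "alpha2": cfg.alpha2,
        "phi": list(cfg.phi),
        "sigma": cfg.sigma,
        "p": p,
        "onset": str(onset.date()),
        "seed": cfg.seed,
    }
    return WeeklySeries(
        dates=dates, values=values, dummy=dummy, infection_rate=c, truth=truth
    )


@dataclass
class EpidemicGenConfig:
    """Ground-truth configuration for the daily epidemic count generator.

    ``daily_tests`` is the number of new tests per day (large by default so
    integer rounding is negligible next to the process noise); the daily
    infection-rate path defaults to a logistic ramp.
    """

    gamma0: float = 0.0008
    gamma1: float = 0.0467
    phi: tuple[float, ...] = (0.87, 0.03)
    sigma: float = 0.003
    n_days: int = 120
    start: str = "2020-03-03"
    lag_days: int = 7
    daily_tests: int = 200_000
    infection_path: np.ndarray | None = None
    infection_range: tuple[float, float] = (0.02, 0.12)
    initial_w: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(abs(f) > 1 for f in self.phi):
            raise ValueError("each AR coefficient must lie in [-1, 1]")
        if self.sigma <= 0 or self.n_days <= self.lag_days:
            raise ValueError("invalid sigma or series shorter than the death lag")


def gen_epidemic_panel(cfg: EpidemicGenConfig) -> DailyEpidemicSeries:
    """Simulate a daily epidemic count panel from a fatality-rate process.

    The simulated rate process (after clipping to [0, 1]) is stored in
    ``.truth["w"]`` together with the generating parameters; running
    ``compute_death_rate`` on the output recovers it up to count rounding
    and the non-decreasing-deaths constraint.
    """
    m = len(cfg.phi)
    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")

    if cfg.infection_path is not None:
        c = np.asarray(cfg.infection_path, dtype=float)
        if len(c) != cfg.n_days:
            raise ValueError("infection_path length must equal n_days")
    else:
        c = _ramp(cfg.n_days, *cfg.infection_range)

    cum_tests = cfg.daily_tests * np.arange(1, cfg.n_days + 1, dtype=np.int64)
    cum_pos = np.round(c * cum_tests).astype(np.int64)
    cum_pos = np.maximum.accumulate(cum_pos)
    cum_pos = np.minimum(cum_pos, cum_tests)

    level = (cfg.gamma0 + cfg.gamma1 * float(c.mean())) / max(1 - sum(cfg.phi), 1e-6)
    init = np.asarray(
        cfg.initial_w if cfg.initial_w is not None else [max(level, 0.0)] * m, float
    )
    if len(init) != m:
        raise ValueError("need one initial value per lag")

    rng = np.random.default_rng(cfg.seed)
    eps = rng.normal(0.0, cfg.sigma, cfg.n_days)
    w = np.concatenate([init, np.zeros(cfg.n_days)])
    cum_deaths = np.zeros(cfg.n_days, dtype=np.int64)
    clipped = 0
    feas_clipped = 0
    prev_deaths = 0
    for t in range(cfg.n_days):
        val = cfg.gamma0 + cfg.gamma1 * c[t] + eps[t]
        for i, f in enumerate(cfg.phi, start=1):
            val += f * w[m + t - i]
        if not 0.0 <= val <= 1.0:
            clipped += 1
            val = min(max(val, 0.0), 1.0)
        if t >= cfg.lag_days:
            # deaths are cumulative, so the rate cannot fall below the level
            # already implied by accumulated deaths and the lagged case count
            denom = cum_pos[t - cfg.lag_days]
            floor = prev_deaths / denom if denom > 0 else 0.0
            if val < floor:
                feas_clipped += 1
                val = min(floor, 1.0)
            cum_deaths[t] = min(int(round(val * denom)), cum_pos[t])
            prev_deaths = cum_deaths[t]
        w[m + t] = val
    w = w[m:]
    if clipped or feas_clipped:
        warnings.warn(
            f"clipped {clipped} fatality-rate draw(s) to [0, 1] and raised "
            f"{feas_clipped} to the cumulative-deaths feasibility floor",
            RuntimeWarning,
            stacklevel=2,
        )

    truth = {
        "gamma0": cfg.gamma0,
        "gamma1": cfg.gamma1,
        "phi": list(cfg.phi),
        "sigma": cfg.sigma,
        "m": m,
        "w": w.tolist(),
        "c": c.tolist(),
        "lag_days": cfg.lag_days,
        "n_clipped": clipped,
        "n_feasibility_clipped": feas_clipped,
        "seed": cfg.seed,
    }
    return DailyEpidemicSeries(
        dates=dates,
        cum_positives=cum_pos,
        cum_tests=cum_tests,
        cum_deaths=cum_deaths,
        truth=truth,
    )
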