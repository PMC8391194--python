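"""Date-indexed series containers and rate construction.

The pipeline works with three kinds of series:

* a **weekly employment panel** — percent employed ``E_t`` on the 0–100
  scale, a binary regime-shift dummy ``d_t`` (1 during recession/pandemic
  windows) and a weekly infection rate ``c_t`` as a fraction in [0, 1]
  (zero before pandemic onset);
* a **daily epidemic count panel** — cumulative confirmed positives,
  cumulative tests and cumulative deaths;
* derived **rate series** — the daily test positivity
  ``c_t = cum_positives_t / cum_tests_t`` and the lagged case-fatality
  rate ``w_t = cum_deaths_t / cum_positives_{t-lag}``.

All rates are stored as fractions in [0, 1]; employment stays on the
percent scale.  Dates are ISO-8601 calendar dates; weeks start Monday.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeeklySeries",
    "DailyEpidemicSeries",
    "RateSeries",
    "compute_infection_rate",
    "compute_death_rate",
    "aggregate_weekly_rate",
    "read_series_csv",
    "write_series_csv",
]

WEEKLY_COLUMNS = ["date", "employment_pct", "infection_rate", "dummy"]
DAILY_COLUMNS = ["date", "cum_positives", "cum_tests", "cum_deaths"]


def _as_datetime_index(dates) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(dates))
    if idx.size and not idx.is_monotonic_increasing:
        raise ValueError("dates must be ascending")
    if idx.size != idx.nunique():
        raise ValueError("dates must be strictly increasing (duplicates found)")
    return idx


@dataclass
class WeeklySeries:
    """Weekly employment panel: E_t (percent), regime dummy d_t, weekly c_t."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    dummy: np.ndarray
    infection_rate: np.ndarray
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dates = _as_datetime_index(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.dummy = np.asarray(self.dummy, dtype=int)
        self.infection_rate = np.asarray(self.infection_rate, dtype=float)
        n = len(self.dates)
        for name in ("values", "dummy", "infection_rate"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match dates")
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 7):
                raise ValueError("weekly dates must have exact 7-day spacing")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("employment values must lie in [0, 100]")
        if np.any((self.infection_rate < 0) | (self.infection_rate > 1)):
            raise ValueError("infection_rate must lie in [0, 1]")
        if not np.isin(self.dummy, (0, 1)).all():
            raise ValueError("dummy must be binary")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "employment_pct": self.values,
                "infection_rate": self.infection_rate,
                "dummy": self.dummy,
            }
        )


@dataclass
class DailyEpidemicSeries:
    """Daily cumulative counts: positives, tests, deaths."""

    dates: pd.DatetimeIndex
    cum_positives: np.ndarray
    cum_tests: np.ndarray
    cum_deaths: np.ndarray
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dates = _as_datetime_index(self.dates)
        for name in ("cum_positives", "cum_tests", "cum_deaths"):
            arr = np.asarray(getattr(self, name))
            if arr.dtype.kind == "f" and not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{name} must be integer counts")
            arr = arr.astype(np.int64)
            setattr(self, name, arr)
            if len(arr) != len(self.dates):
                raise ValueError(f"{name} length does not match dates")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be non-decreasing (cumulative)")
        if np.any(self.cum_positives > self.cum_tests):
            raise ValueError("cum_positives cannot exceed cum_tests")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "cum_positives": self.cum_positives,
                "cum_tests": self.cum_tests,
                "cum_deaths": self.cum_deaths,
            }
        )


@dataclass
class RateSeries:
    """A daily rate series (fractions in [0, 1]) tagged by kind."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    kind: str = "infection"

    def __post_init__(self) -> None:
        self.dates = _as_datetime_index(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.dates):
            raise ValueError("values length does not match dates")
        if self.kind not in ("infection", "death_rate"):
            raise ValueError("kind must be 'infection' or 'death_rate'")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("rates must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.dates)


def compute_infection_rate(series: DailyEpidemicSeries) -> RateSeries:
    """Test positivity: cumulative positives over cumulative tests.

    Days with zero tests and zero positives are dropped; a day with
    positives but no tests is a contradiction and raises ``ValueError``.
    """
    tests = series.cum_tests
    pos = series.cum_positives
    bad = (tests == 0) & (pos > 0)
    if np.any(bad):
        day = series.dates[np.argmax(bad)].date()
        raise ValueError(f"cum_tests is 0 but cum_positives > 0 on {day}")
    keep = tests > 0
    return RateSeries(
        dates=series.dates[keep],
        values=pos[keep] / tests[keep],
        kind="infection",
    )


def compute_death_rate(series: DailyEpidemicSeries, lag_days: int = 7) -> RateSeries:
    """Lagged case-fatality rate w_t = cum_deaths_t / cum_positives_{t-lag}.

    Deaths on day t arise from infections confirmed days earlier, so the
    denominator is the cumulative case count ``lag_days`` before t.  The
    first emitted day is index ``lag_days`` (day lag_days+1 of the series).
    Days whose lagged case count is still zero are dropped with a warning.
    """
    n = len(series)
    if lag_days < 0:
        raise ValueError("lag_days must be non-negative")
    if n <= lag_days:
        return RateSeries(
            dates=series.dates[:0], values=np.empty(0), kind="death_rate"
        )
    deaths = series.cum_deaths[lag_days:]
    cases = series.cum_positives[: n - lag_days]
    dates = series.dates[lag_days:]
    keep = cases > 0
    if not keep.all():
        logger.warning(
            "compute_death_rate: dropped %d day(s) with zero lagged case count",
            int((~keep).sum()),
        )
    values = deaths[keep] / cases[keep]
    if np.any(values > 1):
        warnings.warn(
            "death rate above 1 (deaths exceed lagged cases); clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        values = np.clip(values, 0.0, 1.0)
    return RateSeries(dates=dates[keep], values=values, kind="death_rate")


def aggregate_weekly_rate(
    daily: RateSeries,
    week_starts,
    onset: "pd.Timestamp | str | None" = None,
) -> np.ndarray:
    """Weekly rate = rate on the last observed day of each Monday-start week.

    The last-day convention uses the most recent information available in
    the week.  Weeks that end before ``onset`` (or before the first daily
    observation, if onset is None) are padded with zero — the covariate is
    defined to be zero pre-pandemic.  A post-onset week with no daily
    observation raises ``ValueError``.
    """
    week_starts = pd.DatetimeIndex(pd.to_datetime(week_starts))
    if onset is None:
        onset = daily.dates[0] if len(daily) else None
    else:
        onset = pd.Timestamp(onset)
    s = pd.Series(daily.values, index=daily.dates)
    out = np.zeros(len(week_starts))
    for i, start in enumerate(week_starts):
        end = start + pd.Timedelta(days=6)
        if onset is None or end < onset:
            continue
        window = s.loc[start:end]
        if window.empty:
            raise ValueError(f"no daily rate observations in week starting {start.date()}")
        out[i] = float(window.iloc[-1])
    return out


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_series_csv(path, schema: str) -> "WeeklySeries | DailyEpidemicSeries":
    """Read a weekly or daily panel from CSV.

    ``schema`` is ``"weekly"`` (columns date,employment_pct,infection_rate,
    dummy) or ``"daily"`` (columns date,cum_positives,cum_tests,cum_deaths).
    Validation errors name the offending row.
    """
    if schema not in ("weekly", "daily"):
        raise ValueError("schema must be 'weekly' or 'daily'")
    df = pd.read_csv(path, float_precision="round_trip")
    required = WEEKLY_COLUMNS if schema == "weekly" else DAILY_COLUMNS
    _check_columns(df, required, path)
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparsable date ({exc})") from exc
    try:
        if schema == "weekly":
            return WeeklySeries(
                dates=dates,
                values=df["employment_pct"].to_numpy(),
                dummy=df["dummy"].to_numpy(),
                infection_rate=df["infection_rate"].to_numpy(),
            )
        return DailyEpidemicSeries(
            dates=dates,
            cum_positives=df["cum_positives"].to_numpy(),
            cum_tests=df["cum_tests"].to_numpy(),
            cum_deaths=df["cum_deaths"].to_numpy(),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_series_csv(series: "WeeklySeries | DailyEpidemicSeries", path) -> None:
    """Write a panel to CSV (round-trips exactly through read_series_csv)."""
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    # 17 significant digits guarantee an exact float round trip
    df.to_csv(path, index=False, float_format="%.17g")
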