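"""Monetary benefit and cost construction.

Benefit: a one-step-ahead percent-employed draw ``E`` converts to annual
per-capita income as ``E / 100 * income`` (per-capita annual income, with
an optional relief-adjusted variant).

Cost: relative to a baseline day with death rate ``w0`` and infection rate
``c0``, a reopening day with rates (w, c) changes expected per-capita costs

    medical (three components, i = 1..3):  d_lambda_Si = (w0 c0 - w c) C_Si
    fatality (value of statistical life):  d_lambda_D  = (w c - w0 c0) C_D

so the total incremental cost collapses to

    (w c - w0 c0) * (C_D - C_S1 - C_S2 - C_S3)

With the default assumptions (C_S1 = $2,000, C_S2 = C_S3 = $15,000,
C_D = $7,000,000) the composite multiplier is exactly $6,968,000: the VSL
term dominates the medical components.  Costs can be negative when the
scenario product w*c falls below the baseline product w0*c0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "CostAssumptions",
    "IncomeAssumptions",
    "MonetaryDraws",
    "ComponentCosts",
    "income_from_employment",
    "component_costs",
    "total_cost",
    "load_assumptions",
]

#: Florida baseline on 30 June 2020: death rate 3.48%, infection rate 7.84%.
FL_BASELINE_W0 = 0.0348
FL_BASELINE_C0 = 0.0784

#: Florida 2019 per-capita personal income, and its relief-adjusted variant.
FL_INCOME_ANNUAL = 52_426.0
FL_INCOME_ADJUSTED = 58_371.0


@dataclass
class CostAssumptions:
    """Per-capita cost constants and the baseline rates they are measured from.

    c_s1: testing/treatment for an uninfected symptomatic person.
    c_s2: treatment for an infected patient who recovers.
    c_s3: treatment for an infected patient who dies (taken equal to c_s2).
    c_d:  VSL-based fatality cost.
    w0, c0: baseline death and infection rates (fractions).
    """

    c_s1: float = 2_000.0
    c_s2: float = 15_000.0
    c_s3: float = 15_000.0
    c_d: float = 7_000_000.0
    w0: float = FL_BASELINE_W0
    c0: float = FL_BASELINE_C0

    def __post_init__(self) -> None:
        if min(self.c_s1, self.c_s2, self.c_s3, self.c_d) < 0:
            raise ValueError("costs must be non-negative")
        if self.c_d <= self.c_s1 + self.c_s2 + self.c_s3:
            raise ValueError("fatality cost must exceed the summed medical costs")
        if not (0 <= self.w0 <= 1 and 0 <= self.c0 <= 1):
            raise ValueError("baseline rates must lie in [0, 1]")

    @property
    def composite(self) -> float:
        """The total-cost multiplier C_D - C_S1 - C_S2 - C_S3."""
        return self.c_d - self.c_s1 - self.c_s2 - self.c_s3


@dataclass
class IncomeAssumptions:
    annual: float = FL_INCOME_ANNUAL
    adjusted: float = FL_INCOME_ADJUSTED

    def __post_init__(self) -> None:
        if self.annual <= 0 or self.adjusted <= 0:
            raise ValueError("income measures must be positive")
        if self.adjusted < self.annual:
            raise ValueError("adjusted income cannot be below unadjusted income")


@dataclass
class MonetaryDraws:
    """Dollar-valued draws with provenance."""

    values: np.ndarray
    label: str  # "benefit" or "cost"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("monetary draws must be finite")
        if self.label not in ("benefit", "cost"):
            raise ValueError("label must be 'benefit' or 'cost'")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


class ComponentCosts(NamedTuple):
    d_lambda_s1: float
    d_lambda_s2: float
    d_lambda_s3: float
    d_lambda_d: float

    @property
    def total(self) -> float:
        return sum(self)


def income_from_employment(emp_draws, income: float,
                           provenance: dict | None = None) -> MonetaryDraws:
    """Convert percent-employed draws (0–100 scale) into annual income draws.

    Negative draws — possible in the far tail of the normal predictive —
    are clipped to zero with a warning.
    """
    if income <= 0:
        raise ValueError("income must be positive")
    values = np.asarray(getattr(emp_draws, "values", emp_draws), dtype=float)
    if np.any(values < 0):
        warnings.warn(
            f"clipped {int((values < 0).sum())} negative employment draw(s) to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)
    prov = {"income": income}
    if provenance:
        prov.update(provenance)
    return MonetaryDraws(values / 100.0 * income, "benefit", prov)


def component_costs(w: float, c: float, a: CostAssumptions) -> ComponentCosts:
    """The three medical cost changes and the fatality cost change at rates (w, c)."""
    if not (0 <= w <= 1 and 0 <= c <= 1):
        raise ValueError("rates must lie in [0, 1]")
    delta = a.w0 * a.c0 - w * c
    return ComponentCosts(
        d_lambda_s1=delta * a.c_s1,
        d_lambda_s2=delta * a.c_s2,
        d_lambda_s3=delta * a.c_s3,
        d_lambda_d=-delta * a.c_d,
    )


def total_cost(w_draws, c: float, a: CostAssumptions) -> MonetaryDraws:
    """Total incremental cost draws (w c - w0 c0) * composite for scenario rate c."""
    if not 0 <= c <= 1:
        raise ValueError("scenario infection rate must lie in [0, 1]")
    w = np.asarray(getattr(w_draws, "values", w_draws), dtype=float)
    values = (w * c - a.w0 * a.c0) * a.composite
    return MonetaryDraws(values, "cost", {"infection_rate": c})


def load_assumptions(config: dict) -> tuple[CostAssumptions, IncomeAssumptions]:
    """Build assumption objects from a config mapping.

    Expected keys: ``costs: {c_s1, c_s2, c_s3, c_d}``,
    ``baseline: {w0, c0}``, ``income: {annual, adjusted}``.  Missing keys
    fall back to the Florida defaults.
    """
    costs = dict(config.get("costs", {}))
    baseline = dict(config.get("baseline", {}))
    baseline.pop("date", None)
    income = config.get("income", {})
    return (
        CostAssumptions(**costs, **{k: v for k, v in baseline.items()}),
        IncomeAssumptions(**{k: v for k, v in income.items() if k in ("annual", "adjusted")}),
    )
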