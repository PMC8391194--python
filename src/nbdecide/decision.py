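"""Net-benefit distributions, the threshold decision rule, and policy tables.

The change in net benefit of reopening, dNB = benefit - cost, is simulated
by drawing independently from the (approximately normal) benefit and cost
distributions and subtracting.  The decision rule recommends reopening
("decremental suppression") when mean dNB > 0 **and** P(dNB > 0) >= T,
where the threshold T encodes the decision-maker's risk tolerance.

For policy scenarios, each policy j carries a probability row {pi_jk} over
incremental infection rates k.  The policy's expected benefit is
E(B_j) = sum_k pi_jk * E(B_jk).  Its probability of positive net benefit,
P_j, is computed from the pi-weighted SUM of independent per-rate normal
draws: one draw per rate per sample index, combined as sum_k pi_jk * x_k.
The closed form for that construction is

    P_j = Phi( sum_k pi_jk mu_k / sqrt( sum_k pi_jk^2 sigma_k^2 ) ).

A mixture reading (sum_k pi_jk * P(B_jk > 0)) is available via
``method="mixture"`` but produces materially different probabilities and is
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "NBSummary",
    "ScenarioMatrix",
    "DecisionTable",
    "delta_nb",
    "decide",
    "expected_infection_rate",
    "scenario_expected_benefit",
    "scenario_prob_positive",
    "build_lookup_table",
]


@dataclass
class NBSummary:
    """Summary of a dNB draw distribution for one scenario infection rate."""

    infection_rate: float
    income_label: str
    mean: float
    sd: float
    p2_5: float
    p97_5: float
    p_positive: float
    n_draws: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_positive <= 1:
            raise ValueError("p_positive must lie in [0, 1]")
        if self.p2_5 > self.p97_5:
            raise ValueError("percentiles out of order")


def _mean_sd(x) -> tuple[float, float]:
    if hasattr(x, "values"):
        v = np.asarray(x.values, dtype=float)
        return float(v.mean()), float(v.std(ddof=1))
    mu, sd = x
    return float(mu), float(sd)


def delta_nb(
    benefit,
    cost,
    n_draws: int = 5000,
    seed: int | None = None,
    infection_rate: float = float("nan"),
    income_label: str = "annual",
) -> NBSummary:
    """Simulate the dNB distribution from benefit and cost summaries.

    ``benefit`` and ``cost`` are either draw containers (anything with a
    ``values`` array) or ``(mean, sd)`` pairs; in both cases the benefit and
    cost are resampled as independent normals with those moments and
    subtracted, sample by sample.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    mu_b, sd_b = _mean_sd(benefit)
    mu_c, sd_c = _mean_sd(cost)
    if sd_b < 0 or sd_c < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    b = rng.normal(mu_b, sd_b, n_draws)
    c = rng.normal(mu_c, sd_c, n_draws)
    d = b - c
    lo, hi = np.percentile(d, [2.5, 97.5])
    return NBSummary(
        infection_rate=infection_rate,
        income_label=income_label,
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)),
        p2_5=float(lo),
        p97_5=float(hi),
        p_positive=float(np.mean(d > 0)),
        n_draws=n_draws,
    )


def decide(summary: NBSummary, T: float) -> str:
    """Apply the threshold rule: reopen iff mean dNB > 0 and P(dNB > 0) >= T."""
    if not 0 < T <= 1:
        raise ValueError("threshold T must lie in (0, 1]")
    if summary.mean > 0 and summary.p_positive >= T:
        return "reopen"
    return "do_not_reopen"


@dataclass
class ScenarioMatrix:
    """Probabilities pi_jk of incremental infection rate k under policy j.

    ``rates`` are in percent (e.g. 10, 15, 20, 25); ``probs`` has one row
    per policy, each summing to 1.
    """

    policies: list[str]
    rates: list[float]
    probs: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.policies), len(self.rates)):
            raise ValueError("probs must be (n_policies, n_rates)")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each policy row must sum to 1")

    def row(self, policy: str) -> np.ndarray:
        return self.probs[self.policies.index(policy)]


def _check_row(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("scenario row must be non-negative and sum to 1")
    return w


def expected_infection_rate(weights, rates) -> float:
    """Expected incremental infection rate sum_k pi_jk * k (percent)."""
    w = _check_row(weights)
    rates = np.asarray(rates, dtype=float)
    if len(w) != len(rates):
        raise ValueError("weights and rates lengths differ")
    return float(w @ rates)


def scenario_expected_benefit(nb_means, weights) -> float:
    """E(B_j) = sum_k pi_jk * E(B_jk), rounded to the nearest dollar."""
    w = _check_row(weights)
    means = np.asarray(nb_means, dtype=float)
    if len(means) != len(w):
        raise ValueError("need one dNB mean per infection rate with weight")
    if np.any(~np.isfinite(means[w > 0])):
        raise ValueError("missing dNB mean for a rate with positive weight")
    return float(np.round(w @ means))


def scenario_prob_positive(
    nb_summaries,
    weights,
    n_draws: int = 5000,
    seed: int | None = None,
    method: str = "mc",
) -> float:
    """P_j = P(sum_k pi_jk B_jk > 0) with independent normal B_jk.

    ``nb_summaries`` is a sequence of (mean, sd) pairs aligned with the
    weights.  ``method`` is ``"mc"`` (weighted sum of independent draws),
    ``"analytic"`` (the normal-sum closed form) or ``"mixture"``
    (sum_k pi_jk * Phi(mu_k / sigma_k), a different construction kept for
    comparison).
    """
    w = _check_row(weights)
    mus = np.array([float(m) for m, _ in nb_summaries])
    sds = np.array([float(s) for _, s in nb_summaries])
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    if len(mus) != len(w):
        raise ValueError("summaries and weights lengths differ")
    if method == "analytic":
        mu = w @ mus
        var = (w**2) @ (sds**2)
        if var == 0:
            return float(mu > 0)
        return float(ndtr(mu / np.sqrt(var)))
    if method == "mixture":
        with np.errstate(divide="ignore"):
            z = np.where(sds > 0, mus / np.where(sds > 0, sds, 1.0), np.inf * np.sign(mus))
        return float(w @ ndtr(z))
    if method != "mc":
        raise ValueError("method must be 'mc', 'analytic' or 'mixture'")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mus, sds, size=(n_draws, len(mus)))
    sums = draws @ w
    return float(np.mean(sums > 0))


@dataclass
class DecisionTable:
    """Per-scenario look-up table of E(B_j) and P_j with the chosen policies."""

    scenario: str
    table: pd.DataFrame  # index: policy; columns: expected_benefit, p_positive
    threshold: float
    risk_neutral: str = ""
    risk_averse: str | None = None
    field_order: list[str] = field(default_factory=list)


def build_lookup_table(
    nb_summaries,
    scenarios,
    T: float = 0.90,
    n_draws: int = 5000,
    seed: int | None = None,
    method: str = "mc",
) -> list[DecisionTable]:
    """Build the policy look-up table for each scenario matrix.

    ``nb_summaries`` is a sequence of (mean, sd) pairs, one per infection
    rate on the common rate grid shared by all scenarios.  The risk-neutral
    choice is argmax E(B_j); the risk-averse choice is argmax E(B_j) among
    policies with P_j > T (None if no policy qualifies).  Ties break toward
    the policy listed earlier (least disruptive first).
    """
    if not 0 < T <= 1:
        raise ValueError("threshold T must lie in (0, 1]")
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("need at least one scenario")
    rate_grid = scenarios[0].rates
    for s in scenarios:
        if s.rates != rate_grid:
            raise ValueError("all scenarios must share one infection-rate grid")
    nb_summaries = list(nb_summaries)
    if len(nb_summaries) != len(rate_grid):
        raise ValueError("need one (mean, sd) per infection rate")
    means = [m for m, _ in nb_summaries]

    out = []
    for si, scen in enumerate(scenarios):
        rows = {}
        for pi_, policy in enumerate(scen.policies):
            w = scen.probs[pi_]
            eb = scenario_expected_benefit(means, w)
            pj = scenario_prob_positive(
                nb_summaries, w, n_draws=n_draws,
                seed=None if seed is None else seed + 1000 * si + pi_,
                method=method,
            )
            rows[policy] = {"expected_benefit": eb, "p_positive": round(pj, 4)}
        table = pd.DataFrame.from_dict(rows, orient="index")
        eb_vals = table["expected_benefit"].to_numpy()
        # argmax with ties broken toward the earlier (less disruptive) policy
        neutral = scen.policies[int(np.argmax(eb_vals))]
        eligible = [
            p for p in scen.policies if table.loc[p, "p_positive"] > T
        ]
        averse = None
        if eligible:
            best = max(table.loc[p, "expected_benefit"] for p in eligible)
            averse = next(
                p for p in eligible if table.loc[p, "expected_benefit"] == best
            )
        out.append(
            DecisionTable(
                scenario=scen.name or f"scenario_{si + 1}",
                table=table,
                threshold=T,
                risk_neutral=neutral,
                risk_averse=averse,
                field_order=list(scen.policies),
            )
        )
    return out
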