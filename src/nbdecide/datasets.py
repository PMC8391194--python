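"""Reference tables for the Florida worked example.

These are the published summary numbers for the Florida analysis — the
dNB distribution summaries by scenario infection rate (for both income
measures), the three policy-scenario probability matrices, and the
resulting policy look-up table.  They serve as golden inputs/outputs for
the scenario machinery: the look-up table is reproducible from the dNB
summaries and the scenario matrices alone.
"""

from __future__ import annotations

import pandas as pd

from .decision import ScenarioMatrix

__all__ = [
    "INFECTION_RATES_PCT",
    "florida_delta_nb_table",
    "scenario_matrices",
    "florida_lookup_table",
    "fixture_florida_tables",
]

#: Scenario infection rates considered in the sensitivity analysis (percent).
INFECTION_RATES_PCT = [10.0, 15.0, 20.0, 25.0]

_FL_DNB = {
    "annual": {
        "mean": [42_964.0, 27_295.0, 9_404.0, -8_564.0],
        "sd": [13_186.0, 20_877.0, 28_086.0, 36_438.0],
        "p2_5": [17_654.0, -13_685.0, -44_606.0, -80_608.0],
        "p97_5": [68_504.0, 67_915.0, 63_870.0, 61_562.0],
        "p_positive": [0.9998, 0.8996, 0.6344, 0.4104],
    },
    "adjusted": {
        "mean": [48_666.0, 32_982.0, 15_066.0, -2_914.0],
        "sd": [13_186.0, 20_872.0, 28_085.0, 36_438.0],
        "p2_5": [23_256.0, -7_920.0, -38_876.0, -75_048.0],
        "p97_5": [74_228.0, 73_731.0, 69_423.0, 67_205.0],
        "p_positive": [0.9998, 0.9394, 0.7072, 0.4738],
    },
}

_POLICIES = ["Minor", "Moderate", "Major"]

_SCENARIOS = {
    "scenario_1": {
        "Minor": [0.5, 0.3, 0.1, 0.1],
        "Moderate": [0.2, 0.4, 0.2, 0.2],
        "Major": [0.1, 0.2, 0.4, 0.3],
    },
    "scenario_2": {
        "Minor": [0.3, 0.3, 0.3, 0.1],
        "Moderate": [0.2, 0.3, 0.3, 0.2],
        "Major": [0.1, 0.2, 0.4, 0.3],
    },
    "scenario_3": {
        "Minor": [0.2, 0.4, 0.3, 0.1],
        "Moderate": [0.1, 0.2, 0.4, 0.3],
        "Major": [0.0, 0.1, 0.4, 0.5],
    },
}

#: Published expected incremental infection rate per policy and scenario.
EXPECTED_K = {
    "scenario_1": {"Minor": 14.0, "Moderate": 17.0, "Major": 19.5},
    "scenario_2": {"Minor": 16.0, "Moderate": 17.5, "Major": 19.5},
    "scenario_3": {"Minor": 16.5, "Moderate": 19.5, "Major": 22.0},
}

_LOOKUP = {
    "scenario_1": {
        "Minor": (29_754.0, 0.9988),
        "Moderate": (19_679.0, 0.9372),
        "Major": (10_948.0, 0.7496),
    },
    "scenario_2": {
        "Minor": (23_042.0, 0.9726),
        "Moderate": (17_890.0, 0.913),
        "Major": (10_948.0, 0.7496),
    },
    "scenario_3": {
        "Minor": (21_475.0, 0.953),
        "Moderate": (10_948.0, 0.7496),
        "Major": (2_209.0, 0.5464),
    },
}


def florida_delta_nb_table(income: str = "annual") -> pd.DataFrame:
    """Published Florida dNB summaries, one row per scenario infection rate.

    ``income`` is ``"annual"`` (unadjusted per-capita personal income) or
    ``"adjusted"`` (relief-adjusted).
    """
    if income not in _FL_DNB:
        raise ValueError("income must be 'annual' or 'adjusted'")
    df = pd.DataFrame(_FL_DNB[income])
    df.insert(0, "infection_rate_pct", INFECTION_RATES_PCT)
    return df


def scenario_matrices() -> list[ScenarioMatrix]:
    """The three published policy-scenario probability matrices."""
    out = []
    for name, rows in _SCENARIOS.items():
        out.append(
            ScenarioMatrix(
                policies=list(_POLICIES),
                rates=list(INFECTION_RATES_PCT),
                probs=[rows[p] for p in _POLICIES],
                name=name,
            )
        )
    return out


def florida_lookup_table() -> pd.DataFrame:
    """Published Florida policy look-up table: E(B_j) and P_j per scenario."""
    rows = []
    for scen, vals in _LOOKUP.items():
        for policy, (eb, pj) in vals.items():
            rows.append(
                {"scenario": scen, "policy": policy,
                 "expected_benefit": eb, "p_positive": pj}
            )
    return pd.DataFrame(rows)


def fixture_florida_tables() -> dict:
    """All Florida reference tables in one mapping (for golden tests)."""
    return {
        "delta_nb": {k: florida_delta_nb_table(k) for k in ("annual", "adjusted")},
        "scenarios": scenario_matrices(),
        "expected_k": EXPECTED_K,
        "lookup": florida_lookup_table(),
        "rates_pct": list(INFECTION_RATES_PCT),
    }
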