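"""Incremental costs, ICERs and GDP-threshold classification.

The incremental cost-effectiveness ratio (ICER) of each costing scenario
against current practice is its incremental national cost divided by the
life-years saved (LYS) of an outcome scenario. Following the WHO-CHOICE
GDP-based rule, an ICER at or below 1x GDP per capita is "very
cost-effective", at or below 3x is "cost-effective", and above 3x is "not
cost-effective" (boundaries inclusive). The rule is phrased per DALY
averted; it is applied here per LYS, treating the two as equivalent for
mortality-only gains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .attendance import CostSimulationResult
from .outcomes import HealthGains

__all__ = [
    "CEAConfig",
    "CEAResult",
    "UndefinedICERError",
    "incremental_cost",
    "icer",
    "classify_icer",
    "build_cea_table",
    "cea_table_frame",
    "VERY_COST_EFFECTIVE",
    "COST_EFFECTIVE",
    "NOT_COST_EFFECTIVE",
]

VERY_COST_EFFECTIVE = "very-cost-effective"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not-cost-effective"


class UndefinedICERError(ValueError):
    """Raised when LYS <= 0: the ratio is undefined and dominance analysis
    is out of scope."""


@dataclass(frozen=True)
class CEAConfig:
    """Comparator and threshold inputs.

    The comparator is the current-practice national cost, a fixed input
    from the primary costing study rather than a re-simulated quantity.
    """

    comparator_total_cost: float
    comparator_cost_per_woman: float
    cohort_size: int
    gdp_per_capita: float
    very_ce_multiplier: float = 1.0
    not_ce_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if min(
            self.comparator_total_cost,
            self.comparator_cost_per_woman,
            self.gdp_per_capita,
        ) <= 0:
            raise ValueError("monetary config values must be positive")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if not 0 < self.very_ce_multiplier <= self.not_ce_multiplier:
            raise ValueError("require 0 < very_ce_multiplier <= not_ce_multiplier")


@dataclass
class CEAResult:
    """One cell of the costing x outcome ICER matrix."""

    costing_scenario: str
    outcome_scenario: str
    incremental_cost: float
    lys: float
    icer: float
    classification: str

    @property
    def icer_rounded(self) -> int:
        """ICER rounded half-up to whole dollars, reporting style."""
        return int(math.floor(self.icer + 0.5))

    def to_dict(self) -> dict:
        return {
            "costing_scenario": self.costing_scenario,
            "outcome_scenario": self.outcome_scenario,
            "incremental_cost_usd": self.incremental_cost,
            "lys": self.lys,
            "icer_usd_per_lys": self.icer,
            "icer_usd_per_lys_rounded": self.icer_rounded,
            "classification": self.classification,
        }


def incremental_cost(new_total: float, comparator_total: float) -> float:
    """New-policy total minus comparator total (may be negative)."""
    if new_total < 0 or comparator_total < 0:
        raise ValueError("totals must be non-negative")
    return new_total - comparator_total


def icer(incremental_cost_usd: float, lys: float) -> float:
    """Incremental cost per life-year saved."""
    if lys <= 0:
        raise UndefinedICERError(f"ICER undefined for LYS <= 0 (got {lys})")
    return incremental_cost_usd / lys


def classify_icer(icer_value: float, config: CEAConfig) -> str:
    """GDP-threshold classification of a non-negative ICER."""
    if icer_value < 0:
        raise ValueError("classification requires a non-negative ICER")
    if icer_value <= config.very_ce_multiplier * config.gdp_per_capita:
        return VERY_COST_EFFECTIVE
    if icer_value <= config.not_ce_multiplier * config.gdp_per_capita:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE


def build_cea_table(
    cost_results: Mapping[str, CostSimulationResult] | Sequence[CostSimulationResult],
    gains: Mapping[str, HealthGains] | Sequence[HealthGains],
    config: CEAConfig,
) -> list[CEAResult]:
    """Full cross of costing scenarios x outcome scenarios.

    Every combination is evaluated, including pairings one might consider
    unlikely (e.g. high attendance with pessimistic outcomes): no joint
    model of attendance and effectiveness is assumed.
    """
    if not isinstance(cost_results, Mapping):
        cost_results = {r.scenario_label: r for r in cost_results}
    if not isinstance(gains, Mapping):
        gains = {g.scenario_label: g for g in gains}
    if not cost_results or not gains:
        raise ValueError("need at least one costing and one outcome scenario")

    table = []
    for cost_label, cost_result in cost_results.items():
        delta = incremental_cost(cost_result.mean_total, config.comparator_total_cost)
        for outcome_label, gain in gains.items():
            ratio = icer(delta, gain.total_lys)
            table.append(
                CEAResult(
                    costing_scenario=cost_label,
                    outcome_scenario=outcome_label,
                    incremental_cost=delta,
                    lys=gain.total_lys,
                    icer=ratio,
                    classification=classify_icer(max(ratio, 0.0), config),
                )
            )
    return table


def cea_table_frame(table: Sequence[CEAResult]) -> pd.DataFrame:
    """ICER matrix as a DataFrame: costing scenarios x outcome scenarios."""
    df = pd.DataFrame([r.to_dict() for r in table])
    return df.pivot(
        index="costing_scenario",
        columns="outcome_scenario",
        values="icer_usd_per_lys_rounded",
    )
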