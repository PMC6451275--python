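"""Monte Carlo simulation of antenatal-care attendance and national cost.

Visit counts per woman are modelled as a normal distribution with the
scenario's mean and standard deviation, rounded half-away-from-zero to
integers and clipped to the scenario's [min, max] range. The national cost
of a cohort is the sum of each woman's cumulative visit cost; the whole
procedure is replicated (default 100 times) and the replication spread is
checked as a reliability diagnostic.

:func:`expected_cost_closed_form` evaluates the same discretized-clipped
normal model analytically and serves as an independent oracle for the
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .schedules import VisitCostSchedule

__all__ = [
    "AttendanceScenario",
    "CostSimulationResult",
    "draw_visit_counts",
    "expected_cost_closed_form",
    "simulate_cost_distribution",
    "relative_spread_check",
]


@dataclass(frozen=True)
class AttendanceScenario:
    """Attendance assumptions for one simulated policy world.

    ``degenerate`` marks a full-utilisation counterfactual in which every
    woman attends exactly ``mean_visits`` visits (no randomness).
    """

    label: str
    mean_visits: float
    sd_visits: float
    min_visits: int
    max_visits: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sd_visits < 0:
            raise ValueError("sd_visits must be >= 0")
        if self.min_visits < 1:
            raise ValueError("min_visits must be >= 1")
        if not (self.min_visits <= self.mean_visits <= self.max_visits):
            raise ValueError(
                f"require min_visits <= mean_visits <= max_visits, got "
                f"{self.min_visits} <= {self.mean_visits} <= {self.max_visits}"
            )
        if self.degenerate and float(self.mean_visits) != int(self.mean_visits):
            raise ValueError("degenerate scenario requires an integer mean_visits")
        if not self.degenerate and self.sd_visits == 0:
            raise ValueError("non-degenerate scenario requires sd_visits > 0")


@dataclass
class CostSimulationResult:
    """Summary of a replicated cohort-costing simulation (USD)."""

    scenario_label: str
    n_replications: int
    total_cost_per_replication: np.ndarray  # USD, one entry per replication
    mean_total: float
    min_total: float
    max_total: float
    mean_cost_per_woman: float
    sd_cost_per_woman: float
    relative_spread: float
    cohort_size: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "scenario_label": self.scenario_label,
            "n_replications": int(self.n_replications),
            "cohort_size": int(self.cohort_size),
            "mean_total_usd": self.mean_total,
            "min_total_usd": self.min_total,
            "max_total_usd": self.max_total,
            "mean_cost_per_woman_usd": self.mean_cost_per_woman,
            "sd_cost_per_woman_usd": self.sd_cost_per_woman,
            "relative_spread": self.relative_spread,
            "seed": self.seed,
        }


def _discretize(draws: np.ndarray, scenario: AttendanceScenario) -> np.ndarray:
    # round half-away-from-zero (counts are positive, so floor(x + 0.5)),
    # then clip to the scenario's observed range
    counts = np.floor(draws + 0.5)
    np.clip(counts, scenario.min_visits, scenario.max_visits, out=counts)
    return counts.astype(np.int64)


def draw_visit_counts(
    scenario: AttendanceScenario,
    cohort_size: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw one integer visit count per woman.

    Parameters
    ----------
    scenario
        Attendance assumptions.
    cohort_size
        Number of women (>= 1).
    seed
        Integer seed or a ``numpy.random.Generator``.
    """
    cohort_size = int(cohort_size)
    if cohort_size < 1:
        raise ValueError(f"cohort_size must be >= 1, got {cohort_size}")
    if scenario.degenerate:
        return np.full(cohort_size, int(scenario.mean_visits), dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.normal(scenario.mean_visits, scenario.sd_visits, size=cohort_size)
    return _discretize(draws, scenario)


def visit_count_pmf(scenario: AttendanceScenario) -> tuple[np.ndarray, np.ndarray]:
    """Exact probability mass function of the discretized-clipped normal.

    P(k) for interior k is Phi((k+0.5-mu)/sigma) - Phi((k-0.5-mu)/sigma);
    all tail mass beyond the range folds into ``min_visits`` and
    ``max_visits`` (rounding then clipping).
    """
    ks = np.arange(scenario.min_visits, scenario.max_visits + 1)
    if scenario.degenerate:
        probs = (ks == int(scenario.mean_visits)).astype(float)
        return ks, probs
    mu, sigma = scenario.mean_visits, scenario.sd_visits
    upper = norm.cdf((ks + 0.5 - mu) / sigma)
    lower = norm.cdf((ks - 0.5 - mu) / sigma)
    probs = upper - lower
    probs[0] = upper[0]  # fold lower tail
    probs[-1] = 1.0 - lower[-1]  # fold upper tail
    return ks, probs


def expected_cost_closed_form(
    schedule: VisitCostSchedule, scenario: AttendanceScenario
) -> tuple[float, float]:
    """Exact per-woman cost mean and SD under the attendance model.

    Independent analytic oracle for :func:`simulate_cost_distribution`:
    evaluates the expectation and SD of the cumulative visit cost under the
    discretized-clipped normal visit-count distribution.
    """
    ks, probs = visit_count_pmf(scenario)
    costs = np.array([schedule.cumulative_cost(int(k)) for k in ks])
    mean = float(np.dot(probs, costs))
    var = float(np.dot(probs, (costs - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0))


def simulate_cost_distribution(
    schedule: VisitCostSchedule,
    scenario: AttendanceScenario,
    cohort_size: int,
    n_replications: int = 100,
    seed: int = 0,
) -> CostSimulationResult:
    """Replicated national-cost simulation for one scenario.

    Each replication draws a fresh cohort of visit counts, costs every woman
    with ``schedule`` and sums to a national total. One RNG stream per
    replication is spawned from the master seed, so totals are reproducible
    and independent of execution order. Totals are accumulated in integer
    cents, hence exact.
    """
    cohort_size = int(cohort_size)
    n_replications = int(n_replications)
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")

    lookup = schedule.cost_lookup_cents(scenario.max_visits)
    streams = np.random.SeedSequence(seed).spawn(n_replications)

    totals_cents = np.empty(n_replications, dtype=np.int64)
    sum_cents = 0
    sumsq_cents = 0.0
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        counts = draw_visit_counts(scenario, cohort_size, rng)
        costs = lookup[counts]
        totals_cents[i] = costs.sum()
        sum_cents += int(totals_cents[i])
        sumsq_cents += float(np.dot(costs.astype(float), costs.astype(float)))

    totals = totals_cents / 100.0
    n_women = n_replications * cohort_size
    mean_per_woman = (sum_cents / n_women) / 100.0
    var_per_woman = sumsq_cents / n_women / 100.0**2 - mean_per_woman**2
    sd_per_woman = math.sqrt(max(var_per_woman, 0.0))

    mean_total = float(totals.mean())
    min_total = float(totals.min())
    max_total = float(totals.max())
    spread = (max_total - min_total) / mean_total if mean_total > 0 else 0.0

    return CostSimulationResult(
        scenario_label=scenario.label,
        n_replications=n_replications,
        total_cost_per_replication=totals,
        mean_total=mean_total,
        min_total=min_total,
        max_total=max_total,
        mean_cost_per_woman=mean_per_woman,
        sd_cost_per_woman=sd_per_woman,
        relative_spread=spread,
        cohort_size=cohort_size,
        seed=seed,
    )


def relative_spread_check(
    result: CostSimulationResult, threshold: float = 0.002
) -> tuple[bool, float]:
    """Reliability diagnostic: is (max - min)/mean below ``threshold``?

    Returns ``(passed, spread)``. Requires at least two replications.
    """
    if result.n_replications < 2:
        raise ValueError("spread check requires at least 2 replications")
    spread = result.relative_spread
    return spread < threshold, spread
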