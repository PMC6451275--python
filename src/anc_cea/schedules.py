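"""Antenatal-care visit schedules and per-woman cumulative costing.

A schedule is an ordered list of per-visit unit costs (2015 USD). Attending
``k`` visits is modelled as receiving the content of scheduled visits
``1..k`` in order; visits beyond the scheduled count (possible when the
attendance range extends past the schedule, e.g. a 9th--11th visit under an
eight-contact policy) are each costed at a flat overflow price, by default
the cheapest recurring routine-visit price.

Money is held internally as integer cents so cohort totals are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidAttendanceError",
    "VisitCostSchedule",
    "cumulative_cost",
    "full_compliance_cost",
]


class InvalidAttendanceError(ValueError):
    """Raised for visit counts below one (the cohort is defined as women
    who attend antenatal care at least once)."""


def _to_cents(amount: float) -> int:
    cents = round(float(amount) * 100)
    return int(cents)


@dataclass(frozen=True)
class VisitCostSchedule:
    """An ordered per-visit cost schedule.

    Parameters
    ----------
    label
        Human-readable name, e.g. ``"eight-visit"``.
    unit_costs
        Unit cost in USD of each scheduled visit, in visit order.
    overflow_visit_cost
        Cost in USD of each visit beyond the scheduled count. Defaults to
        $6, the routine-visit price (no additional tests are scheduled for
        such visits).
    """

    label: str
    unit_costs: tuple[float, ...]
    overflow_visit_cost: float = 6.0
    _unit_cents: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        costs = tuple(float(c) for c in self.unit_costs)
        if len(costs) == 0:
            raise ValueError("schedule must contain at least one visit")
        if any(c < 0 for c in costs):
            raise ValueError("unit costs must be non-negative")
        if self.overflow_visit_cost < 0:
            raise ValueError("overflow visit cost must be non-negative")
        object.__setattr__(self, "unit_costs", costs)
        object.__setattr__(self, "_unit_cents", tuple(_to_cents(c) for c in costs))

    @property
    def n_scheduled(self) -> int:
        """Number of scheduled visits."""
        return len(self.unit_costs)

    @property
    def overflow_cents(self) -> int:
        return _to_cents(self.overflow_visit_cost)

    def cumulative_cents(self, n_visits: int) -> int:
        """Exact cost, in cents, of attending visits ``1..n_visits``."""
        n_visits = int(n_visits)
        if n_visits < 1:
            raise InvalidAttendanceError(
                f"n_visits must be >= 1, got {n_visits}: the cohort comprises "
                "women attending at least one visit"
            )
        scheduled = sum(self._unit_cents[: min(n_visits, self.n_scheduled)])
        extra = max(0, n_visits - self.n_scheduled)
        return scheduled + extra * self.overflow_cents

    def cumulative_cost(self, n_visits: int) -> float:
        """Cost in USD of attending visits ``1..n_visits``.

        Visits past the schedule length each add ``overflow_visit_cost``.
        """
        return self.cumulative_cents(n_visits) / 100.0

    def full_compliance_cost(self) -> float:
        """Cost in USD of attending exactly the scheduled number of visits."""
        return self.cumulative_cost(self.n_scheduled)

    def cost_lookup_cents(self, max_visits: int) -> np.ndarray:
        """Cumulative-cost lookup table in cents, indexed by visit count.

        ``table[k]`` is the cost of ``k`` visits for ``k >= 1``; index 0 is
        unused and set to 0. Used to vectorize cohort costing.
        """
        max_visits = int(max_visits)
        if max_visits < 1:
            raise InvalidAttendanceError("max_visits must be >= 1")
        table = np.zeros(max_visits + 1, dtype=np.int64)
        for k in range(1, max_visits + 1):
            table[k] = self.cumulative_cents(k)
        return table


def cumulative_cost(schedule: VisitCostSchedule, n_visits: int) -> float:
    """Cost in USD of a woman attending visits ``1..n_visits`` of ``schedule``."""
    return schedule.cumulative_cost(n_visits)


def full_compliance_cost(schedule: VisitCostSchedule) -> float:
    """Per-woman cost in USD under full compliance with ``schedule``."""
    return schedule.full_compliance_cost()
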