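"""Deaths averted and discounted life-years saved (LYS).

A scenario mortality reduction is applied to baseline annual death counts
to give deaths averted over a one-year implementation period. Each averted
death contributes the present value of its remaining life expectancy,
discounted at an annual rate with a standard end-of-year annuity:

    A(n, r) = (1 - (1 + r)^-n) / r        (A(n, 0) = n)

Perinatal deaths use a single horizon (life expectancy at birth); maternal
deaths use the remaining female life expectancy per age group, weighted by
the age distribution of maternal deaths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .elicitation import OutcomeScenario

__all__ = [
    "BaselineEpidemiology",
    "HealthGains",
    "deaths_averted",
    "annuity_factor",
    "perinatal_lys",
    "maternal_lys",
    "maternal_years_per_death",
    "health_gains",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BaselineEpidemiology:
    """Baseline mortality and life-table inputs.

    ``perinatal_discount_horizon_years`` is the horizon over which a
    perinatal death's life-years are discounted. Two conventions ship with
    the package: the "stated" variant uses life expectancy at birth for
    both sexes (64 years); the "implied" variant uses 66 years, the horizon
    consistent with the published life-years figures (see docs/methods.md).

    ``maternal_age_distribution`` is a sequence of ``(age midpoint, share)``
    pairs for the age distribution of maternal deaths; shares must sum to 1
    and every midpoint must lie below female life expectancy.
    """

    annual_perinatal_deaths: int
    annual_maternal_deaths: int
    life_expectancy_both_sexes: float = 64.0
    life_expectancy_female: float = 66.0
    discount_rate: float = 0.03
    perinatal_discount_horizon_years: int = 66
    maternal_age_distribution: tuple[tuple[float, float], ...] = ()
    perinatal_mortality_rate: float | None = None  # per 1000 pregnancies, descriptive
    maternal_mortality_ratio: float | None = None  # per 100,000 live births, descriptive

    def __post_init__(self) -> None:
        if self.annual_perinatal_deaths < 0 or self.annual_maternal_deaths < 0:
            raise ValueError("death counts must be non-negative")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must lie in [0, 1)")
        dist = tuple((float(m), float(s)) for m, s in self.maternal_age_distribution)
        if dist:
            total = sum(s for _, s in dist)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"maternal age shares must sum to 1, got {total}")
            for midpoint, share in dist:
                if share < 0:
                    raise ValueError("maternal age shares must be non-negative")
                if midpoint >= self.life_expectancy_female:
                    raise ValueError(
                        f"age midpoint {midpoint} is not below female life "
                        f"expectancy {self.life_expectancy_female}"
                    )
        object.__setattr__(self, "maternal_age_distribution", dist)


@dataclass
class HealthGains:
    """Deaths averted and discounted LYS for one outcome scenario."""

    scenario_label: str
    perinatal_deaths_averted: int
    maternal_deaths_averted: int
    perinatal_lys: float
    maternal_lys: float

    @property
    def total_lys(self) -> float:
        return self.perinatal_lys + self.maternal_lys

    def to_dict(self) -> dict:
        return {
            "scenario_label": self.scenario_label,
            "perinatal_deaths_averted": self.perinatal_deaths_averted,
            "maternal_deaths_averted": self.maternal_deaths_averted,
            "perinatal_lys": self.perinatal_lys,
            "maternal_lys": self.maternal_lys,
            "total_lys": self.total_lys,
        }


def deaths_averted(baseline_deaths: int, reduction_pct: float) -> int:
    """Deaths averted by a percentage mortality reduction, rounded half-up."""
    if baseline_deaths < 0:
        raise ValueError("baseline_deaths must be non-negative")
    if not 0.0 <= reduction_pct <= 100.0:
        raise ValueError(f"reduction_pct must lie in [0, 100], got {reduction_pct}")
    return _round_half_up(baseline_deaths * reduction_pct / 100.0)


def annuity_factor(horizon_years: int, discount_rate: float) -> float:
    """Present value of one life-year per year over ``horizon_years``.

    End-of-year convention: A(n, r) = (1 - (1+r)^-n)/r, with A(n, 0) = n.
    """
    if horizon_years < 0:
        raise ValueError("horizon_years must be >= 0")
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    n = int(horizon_years)
    if discount_rate == 0:
        return float(n)
    r = float(discount_rate)
    return (1.0 - (1.0 + r) ** (-n)) / r


def perinatal_lys(deaths: int, baseline: BaselineEpidemiology) -> float:
    """Discounted LYS from averted perinatal deaths."""
    return deaths * annuity_factor(
        baseline.perinatal_discount_horizon_years, baseline.discount_rate
    )


def maternal_years_per_death(baseline: BaselineEpidemiology) -> float:
    """Discounted life-years per averted maternal death.

    Age-share-weighted annuity over each group's remaining female life
    expectancy (rounded half-up to whole years).
    """
    if not baseline.maternal_age_distribution:
        raise ValueError("baseline has no maternal age distribution")
    total = 0.0
    for midpoint, share in baseline.maternal_age_distribution:
        horizon = _round_half_up(baseline.life_expectancy_female - midpoint)
        total += share * annuity_factor(horizon, baseline.discount_rate)
    return total


def maternal_lys(deaths: int, baseline: BaselineEpidemiology) -> float:
    """Discounted LYS from averted maternal deaths."""
    return deaths * maternal_years_per_death(baseline)


def health_gains(
    baseline: BaselineEpidemiology, scenario: OutcomeScenario
) -> HealthGains:
    """Deaths averted and LYS for one outcome scenario."""
    peri_averted = deaths_averted(
        baseline.annual_perinatal_deaths, scenario.perinatal_reduction_pct
    )
    mat_averted = deaths_averted(
        baseline.annual_maternal_deaths, scenario.maternal_reduction_pct
    )
    return HealthGains(
        scenario_label=scenario.label,
        perinatal_deaths_averted=peri_averted,
        maternal_deaths_averted=mat_averted,
        perinatal_lys=perinatal_lys(peri_averted, baseline),
        maternal_lys=maternal_lys(mat_averted, baseline),
    )
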