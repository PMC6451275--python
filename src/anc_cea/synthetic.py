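"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without any external
data:

* an expert panel whose two-round responses, after Delphi merging and
  half-split aggregation, reproduce configurable scenario targets exactly
  (inverse design: the half means are fixed first, then panel members are
  spread around them mean-preservingly);
* a current-practice attendance survey (discretized clipped normal visit
  counts, defaults mean 3.3 / SD 0.8);
* a synthetic maternal-death age distribution calibrated so the implied
  discounted life-years per maternal death hits a target factor — a
  stand-in for the unavailable primary age table.

:func:`rwanda_reference_config` bundles the full Rwanda 2015 reference
inputs (unit-cost schedules, attendance scenarios, outcome scenarios,
baseline epidemiology and thresholds) into a ready-to-run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attendance import AttendanceScenario, draw_visit_counts
from .elicitation import ExpertResponse
from .outcomes import annuity_factor
from .schedules import VisitCostSchedule

__all__ = [
    "PanelSpec",
    "SurveySpec",
    "generate_expert_panel",
    "generate_attendance_survey",
    "calibrated_maternal_age_shares",
    "MATERNAL_YEARS_PER_DEATH_TARGET",
    "four_visit_schedule",
    "eight_visit_schedule",
    "rwanda_attendance_scenarios",
    "rwanda_reference_config",
]

#: Discounted life-years per averted maternal death that the synthetic age
#: distribution is calibrated to reproduce (optimistic-scenario ratio
#: 4044 LYS / 195 deaths).
MATERNAL_YEARS_PER_DEATH_TARGET = 4044.0 / 195.0


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic two-round expert panel."""

    n_experts: int = 8
    target_pessimistic: tuple[float, float] = (22.5, 7.0)  # (perinatal, maternal) %
    target_optimistic: tuple[float, float] = (55.0, 52.5)
    revision_fraction: float = 0.625  # 5 of 8 experts revised in round 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 2 or self.n_experts % 2:
            raise ValueError("n_experts must be an even number >= 2")
        if not 0.0 <= self.revision_fraction <= 1.0:
            raise ValueError("revision_fraction must lie in [0, 1]")
        for pess, opt in zip(self.target_pessimistic, self.target_optimistic):
            if not (0.0 <= pess <= 100.0 and 0.0 <= opt <= 100.0):
                raise ValueError("targets must lie in [0, 100]")
            if opt < pess:
                raise ValueError(
                    f"optimistic target {opt} below pessimistic target {pess}"
                )


@dataclass(frozen=True)
class SurveySpec:
    """Specification of a synthetic attendance survey."""

    n_women: int
    mean_visits: float = 3.3
    sd_visits: float = 0.8
    min_visits: int = 1
    max_visits: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        if not self.min_visits <= self.mean_visits <= self.max_visits:
            raise ValueError("mean_visits must lie within [min_visits, max_visits]")


def _half_values(
    pess_mean: float, opt_mean: float, m: int, rng: np.random.Generator
) -> np.ndarray:
    """2m values whose lower-half mean is ``pess_mean`` and upper-half mean
    ``opt_mean`` exactly.

    Each half is an arithmetic spread around its mean; symmetric offsets
    cancel pairwise, so the half means are exact in floating point. The
    spread widths are drawn at random within the feasible range keeping the
    halves ordered and inside [0, 100].
    """
    if m == 1:
        return np.array([pess_mean, opt_mean])
    gap = opt_mean - pess_mean
    half_span = (m - 1) / 2.0
    # widest step keeping lower half <= midpoint of the gap and within [0, 100]
    d_low_max = min(gap / 2.0, pess_mean) / half_span if half_span else 0.0
    d_up_max = min(gap / 2.0, 100.0 - opt_mean) / half_span if half_span else 0.0
    d_low = rng.uniform(0.3, 1.0) * d_low_max
    d_up = rng.uniform(0.3, 1.0) * d_up_max
    offsets = np.arange(m) - half_span
    return np.concatenate([pess_mean + d_low * offsets, opt_mean + d_up * offsets])


def generate_expert_panel(spec: PanelSpec) -> list[ExpertResponse]:
    """Generate a two-round expert-response collection.

    The round-2 (final) values are constructed so that merging rounds and
    half-splitting each indicator recovers ``spec.target_pessimistic`` and
    ``spec.target_optimistic`` exactly. A ``revision_fraction`` of experts
    revised between rounds (their round-1 values differ); the rest gave
    their final answer in round 1 and have no round-2 entry, which the
    merge treats as confirmation.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_experts // 2

    peri = _half_values(spec.target_pessimistic[0], spec.target_optimistic[0], m, rng)
    mat = _half_values(spec.target_pessimistic[1], spec.target_optimistic[1], m, rng)
    # pair indicators independently across experts: an expert may be
    # pessimistic about one indicator and optimistic about the other
    mat = rng.permutation(mat)

    n_revising = int(round(spec.revision_fraction * spec.n_experts))
    revisers = set(rng.choice(spec.n_experts, size=n_revising, replace=False).tolist())

    responses: list[ExpertResponse] = []
    for i in range(spec.n_experts):
        expert_id = f"E{i + 1:02d}"
        final_p, final_m = float(peri[i]), float(mat[i])
        if i in revisers:
            jitter = rng.uniform(-10.0, 10.0, size=2)
            responses.append(
                ExpertResponse(
                    expert_id,
                    1,
                    float(np.clip(final_p + jitter[0], 0.0, 100.0)),
                    float(np.clip(final_m + jitter[1], 0.0, 100.0)),
                )
            )
            responses.append(ExpertResponse(expert_id, 2, final_p, final_m))
        else:
            responses.append(ExpertResponse(expert_id, 1, final_p, final_m))
    return responses


def _latent_sd_for_observed_sd(spec: SurveySpec) -> float:
    """Latent normal SD whose discretized-clipped counts have the target SD.

    Rounding to integers inflates the observed SD (roughly by sqrt(1/12) in
    quadrature), so the latent SD is solved from the exact count pmf to make
    the *observed* survey moments match the specification.
    """
    from scipy.optimize import brentq

    from .attendance import visit_count_pmf

    def observed_sd(latent_sd: float) -> float:
        scenario = AttendanceScenario(
            "cal", spec.mean_visits, latent_sd, spec.min_visits, spec.max_visits
        )
        ks, probs = visit_count_pmf(scenario)
        mean = float(np.dot(probs, ks))
        return float(np.sqrt(np.dot(probs, (ks - mean) ** 2)))

    lo, hi = 1e-3, 2.0 * spec.sd_visits + 1.0
    if observed_sd(lo) >= spec.sd_visits:
        return lo
    return float(brentq(lambda s: observed_sd(s) - spec.sd_visits, lo, hi, xtol=1e-6))


def generate_attendance_survey(spec: SurveySpec) -> np.ndarray:
    """Per-woman visit counts for a synthetic current-practice survey.

    Reuses the simulation's discretized-clipped-normal convention so one
    rounding rule holds repo-wide; the latent normal SD is calibrated so the
    generated counts recover the spec's mean and SD (the survey targets are
    observed moments of integer counts, not latent parameters).
    """
    if spec.sd_visits == 0:
        scenario = AttendanceScenario(
            "survey", spec.mean_visits, 0.0, spec.min_visits, spec.max_visits,
            degenerate=True,
        )
        return draw_visit_counts(scenario, spec.n_women, spec.seed)
    scenario = AttendanceScenario(
        label="survey",
        mean_visits=spec.mean_visits,
        sd_visits=_latent_sd_for_observed_sd(spec),
        min_visits=spec.min_visits,
        max_visits=spec.max_visits,
    )
    return draw_visit_counts(scenario, spec.n_women, spec.seed)


# ---------------------------------------------------------------------------
# Synthetic maternal-death age distribution
# ---------------------------------------------------------------------------

_AGE_MIDPOINTS = (17.5, 22.5, 27.5, 32.5, 37.5, 42.5, 47.5)
# anchor share vectors over 5-year reproductive age groups (15-49):
# a younger-skewed and an older-skewed plausible profile
_SHARES_YOUNG = (0.06, 0.16, 0.21, 0.23, 0.19, 0.12, 0.03)
_SHARES_OLD = (0.03, 0.11, 0.18, 0.22, 0.23, 0.16, 0.07)


def _factor(shares, midpoints, rate, le_female) -> float:
    return sum(
        s * annuity_factor(int(np.floor(le_female - m + 0.5)), rate)
        for m, s in zip(midpoints, shares)
    )


def calibrated_maternal_age_shares(
    target_years_per_death: float = MATERNAL_YEARS_PER_DEATH_TARGET,
    discount_rate: float = 0.03,
    life_expectancy_female: float = 66.0,
) -> tuple[tuple[float, float], ...]:
    """Synthetic maternal-death age distribution hitting a target factor.

    The discounted years-per-death factor is linear in the age shares, so an
    exact calibration is obtained by blending a younger- and an older-skewed
    anchor profile: solve for the blend weight that makes the share-weighted
    annuity equal ``target_years_per_death``. Raises if the target lies
    outside the range the two anchors span.

    Returns ``((midpoint, share), ...)`` suitable for
    :class:`~anc_cea.outcomes.BaselineEpidemiology`.
    """
    f_young = _factor(_SHARES_YOUNG, _AGE_MIDPOINTS, discount_rate, life_expectancy_female)
    f_old = _factor(_SHARES_OLD, _AGE_MIDPOINTS, discount_rate, life_expectancy_female)
    lo, hi = min(f_young, f_old), max(f_young, f_old)
    if not lo <= target_years_per_death <= hi:
        raise ValueError(
            f"target factor {target_years_per_death:.3f} outside the "
            f"calibratable range [{lo:.3f}, {hi:.3f}]"
        )
    lam = (target_years_per_death - f_old) / (f_young - f_old)
    shares = tuple(
        lam * y + (1.0 - lam) * o for y, o in zip(_SHARES_YOUNG, _SHARES_OLD)
    )
    return tuple(zip(_AGE_MIDPOINTS, shares))


# ---------------------------------------------------------------------------
# Rwanda 2015 reference fixture
# ---------------------------------------------------------------------------


def four_visit_schedule() -> VisitCostSchedule:
    """Current Rwandan four-visit schedule (2015 USD unit costs)."""
    return VisitCostSchedule("four-visit", (21, 6, 6, 11), overflow_visit_cost=6.0)


def eight_visit_schedule(overflow_visit_cost: float = 6.0) -> VisitCostSchedule:
    """2016 WHO eight-contact schedule (2015 USD unit costs).

    Visit 1 adds a $3 obstetric ultrasound to the current $21 first visit;
    visits 3 and 6 add repeat bacteriuria ($3) and anaemia ($0.75) tests to
    the $6 routine visit (printed as $10); the last visit matches the
    current model's $11.
    """
    return VisitCostSchedule(
        "eight-visit", (24, 6, 10, 6, 6, 10, 6, 11), overflow_visit_cost
    )


def rwanda_attendance_scenarios() -> list[AttendanceScenario]:
    """The three eight-contact attendance scenarios plus full utilisation
    of the current four-visit policy."""
    return [
        AttendanceScenario("scenario-1", 5.0, 0.8, 1, 8),
        AttendanceScenario("scenario-2", 6.0, 0.8, 2, 10),
        AttendanceScenario("scenario-3", 7.0, 0.8, 3, 11),
        AttendanceScenario("full-utilisation", 4.0, 0.0, 4, 4, degenerate=True),
    ]


def rwanda_reference_config(variant: str = "implied", seed: int = 20150):
    """Complete Rwanda 2015 run configuration.

    ``variant`` selects the perinatal discounting horizon: ``"stated"``
    uses life expectancy at birth for both sexes (64 years); ``"implied"``
    uses the 66-year horizon consistent with the published life-years
    figures. See docs/methods.md.
    """
    from .config import RunConfig  # local import to avoid a cycle

    age_dist = calibrated_maternal_age_shares()
    return RunConfig.model_validate(
        {
            "label": "rwanda-2015",
            "variant": variant,
            "seed": seed,
            "n_replications": 100,
            "cohort_size": 373_679,
            "schedules": [
                {
                    "label": "four-visit",
                    "unit_costs_usd": [21, 6, 6, 11],
                    "overflow_visit_cost_usd": 6.0,
                },
                {
                    "label": "eight-visit",
                    "unit_costs_usd": [24, 6, 10, 6, 6, 10, 6, 11],
                    "overflow_visit_cost_usd": 6.0,
                },
            ],
            "attendance_scenarios": [
                {
                    "label": "scenario-1",
                    "schedule": "eight-visit",
                    "mean_visits": 5,
                    "sd_visits": 0.8,
                    "min_visits": 1,
                    "max_visits": 8,
                },
                {
                    "label": "scenario-2",
                    "schedule": "eight-visit",
                    "mean_visits": 6,
                    "sd_visits": 0.8,
                    "min_visits": 2,
                    "max_visits": 10,
                },
                {
                    "label": "scenario-3",
                    "schedule": "eight-visit",
                    "mean_visits": 7,
                    "sd_visits": 0.8,
                    "min_visits": 3,
                    "max_visits": 11,
                },
                {
                    "label": "full-utilisation",
                    "schedule": "four-visit",
                    "mean_visits": 4,
                    "sd_visits": 0.0,
                    "min_visits": 4,
                    "max_visits": 4,
                    "degenerate": True,
                    "include_in_cea": False,
                },
            ],
            "outcomes": {
                "source": "explicit",
                "scenarios": [
                    {
                        "label": "pessimistic",
                        "perinatal_reduction_pct": 22.5,
                        "maternal_reduction_pct": 7.0,
                    },
                    {
                        "label": "optimistic",
                        "perinatal_reduction_pct": 55.0,
                        "maternal_reduction_pct": 52.5,
                    },
                ],
            },
            "baseline": {
                "annual_perinatal_deaths": 10_076,
                "annual_maternal_deaths": 371,
                "perinatal_mortality_rate_per_1000": 29.0,
                "maternal_mortality_ratio_per_100k": 210.0,
                "life_expectancy_both_sexes_years": 64.0,
                "life_expectancy_female_years": 66.0,
                "discount_rate": 0.03,
                "maternal_age_distribution": [
                    {"midpoint_years": m, "share": s} for m, s in age_dist
                ],
            },
            "cea": {
                "comparator_total_cost_usd": 13_939_970,
                "comparator_cost_per_woman_usd": 37.0,
                "gdp_per_capita_usd": 697.0,
            },
        }
    )
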