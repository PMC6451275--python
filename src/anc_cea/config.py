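"""Run configuration: schema, validation and domain-object construction.

A run is described by a single YAML (or JSON) document. Field names carry
explicit units (``*_usd``, ``*_pct``, ``*_years``) because the analysis is
parameter-dense and silent unit errors are the main failure mode. Pydantic
validates the schema and reports every violating field path at once.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .attendance import AttendanceScenario
from .engine import CEAConfig
from .outcomes import BaselineEpidemiology
from .schedules import VisitCostSchedule

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for an invalid or unreadable run configuration."""


class ScheduleSpec(BaseModel):
    label: str
    unit_costs_usd: list[float] = Field(min_length=1)
    overflow_visit_cost_usd: float = 6.0

    @field_validator("unit_costs_usd")
    @classmethod
    def _non_negative(cls, v: list[float]) -> list[float]:
        if any(c < 0 for c in v):
            raise ValueError("unit costs must be non-negative")
        return v

    @field_validator("overflow_visit_cost_usd")
    @classmethod
    def _overflow_non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("overflow visit cost must be non-negative")
        return v

    def to_domain(self) -> VisitCostSchedule:
        return VisitCostSchedule(
            self.label, tuple(self.unit_costs_usd), self.overflow_visit_cost_usd
        )


class AttendanceSpec(BaseModel):
    label: str
    schedule: str
    mean_visits: float
    sd_visits: float = 0.8
    min_visits: int = Field(ge=1)
    max_visits: int
    degenerate: bool = False
    include_in_cea: bool = True  # full-utilisation rows are costed but not ICER'd

    def to_domain(self) -> AttendanceScenario:
        return AttendanceScenario(
            label=self.label,
            mean_visits=self.mean_visits,
            sd_visits=self.sd_visits,
            min_visits=self.min_visits,
            max_visits=self.max_visits,
            degenerate=self.degenerate,
        )


class OutcomeScenarioSpec(BaseModel):
    label: str
    perinatal_reduction_pct: float = Field(ge=0, le=100)
    maternal_reduction_pct: float = Field(ge=0, le=100)


class OutcomesSpec(BaseModel):
    source: Literal["explicit", "expert_csv"] = "explicit"
    expert_csv: Optional[str] = None
    scenarios: list[OutcomeScenarioSpec] = []

    @model_validator(mode="after")
    def _check_source(self) -> "OutcomesSpec":
        if self.source == "explicit" and len(self.scenarios) < 1:
            raise ValueError("explicit outcome source requires at least one scenario")
        if self.source == "expert_csv" and not self.expert_csv:
            raise ValueError("expert_csv outcome source requires an expert_csv path")
        return self


class AgeGroupSpec(BaseModel):
    midpoint_years: float = Field(ge=0)
    share: float = Field(ge=0, le=1)


class BaselineSpec(BaseModel):
    annual_perinatal_deaths: int = Field(ge=0)
    annual_maternal_deaths: int = Field(ge=0)
    life_expectancy_both_sexes_years: float = 64.0
    life_expectancy_female_years: float = 66.0
    discount_rate: float = Field(default=0.03, ge=0, lt=1)
    maternal_age_distribution: list[AgeGroupSpec] = Field(min_length=1)
    perinatal_mortality_rate_per_1000: Optional[float] = None
    maternal_mortality_ratio_per_100k: Optional[float] = None

    def to_domain(self, perinatal_horizon_years: int) -> BaselineEpidemiology:
        return BaselineEpidemiology(
            annual_perinatal_deaths=self.annual_perinatal_deaths,
            annual_maternal_deaths=self.annual_maternal_deaths,
            life_expectancy_both_sexes=self.life_expectancy_both_sexes_years,
            life_expectancy_female=self.life_expectancy_female_years,
            discount_rate=self.discount_rate,
            perinatal_discount_horizon_years=perinatal_horizon_years,
            maternal_age_distribution=tuple(
                (g.midpoint_years, g.share) for g in self.maternal_age_distribution
            ),
            perinatal_mortality_rate=self.perinatal_mortality_rate_per_1000,
            maternal_mortality_ratio=self.maternal_mortality_ratio_per_100k,
        )


class CEASpec(BaseModel):
    comparator_total_cost_usd: float = Field(gt=0)
    comparator_cost_per_woman_usd: float = Field(gt=0)
    gdp_per_capita_usd: float = Field(gt=0)
    very_ce_multiplier: float = 1.0
    not_ce_multiplier: float = 3.0

    def to_domain(self, cohort_size: int) -> CEAConfig:
        return CEAConfig(
            comparator_total_cost=self.comparator_total_cost_usd,
            comparator_cost_per_woman=self.comparator_cost_per_woman_usd,
            cohort_size=cohort_size,
            gdp_per_capita=self.gdp_per_capita_usd,
            very_ce_multiplier=self.very_ce_multiplier,
            not_ce_multiplier=self.not_ce_multiplier,
        )


class RunConfig(BaseModel):
    """Fully validated description of one end-to-end run."""

    label: str = "run"
    variant: Literal["stated", "implied"] = "implied"
    seed: int = 20150
    n_replications: int = Field(default=100, ge=1)
    cohort_size: int = Field(gt=0)
    schedules: list[ScheduleSpec] = Field(min_length=1)
    attendance_scenarios: list[AttendanceSpec] = Field(min_length=1)
    outcomes: OutcomesSpec
    baseline: BaselineSpec
    cea: CEASpec

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        schedule_labels = [s.label for s in self.schedules]
        if len(set(schedule_labels)) != len(schedule_labels):
            raise ValueError("schedule labels must be unique")
        scenario_labels = [a.label for a in self.attendance_scenarios]
        if len(set(scenario_labels)) != len(scenario_labels):
            raise ValueError("attendance scenario labels must be unique")
        for a in self.attendance_scenarios:
            if a.schedule not in schedule_labels:
                raise ValueError(
                    f"attendance scenario {a.label!r} references unknown "
                    f"schedule {a.schedule!r}"
                )
        outcome_labels = [s.label for s in self.outcomes.scenarios]
        if len(set(outcome_labels)) != len(outcome_labels):
            raise ValueError("outcome scenario labels must be unique")
        return self

    @property
    def perinatal_horizon_years(self) -> int:
        """Perinatal discounting horizon for the active variant.

        "stated": life expectancy at birth for both sexes. "implied": the
        female life expectancy at birth (66), the horizon consistent with
        the reference life-years figures.
        """
        if self.variant == "stated":
            return int(round(self.baseline.life_expectancy_both_sexes_years))
        return int(round(self.baseline.life_expectancy_female_years))

    def schedule_map(self) -> dict[str, VisitCostSchedule]:
        return {s.label: s.to_domain() for s in self.schedules}

    def baseline_domain(self) -> BaselineEpidemiology:
        return self.baseline.to_domain(self.perinatal_horizon_years)

    def cea_domain(self) -> CEAConfig:
        return self.cea.to_domain(self.cohort_size)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Schema violations raise :class:`ConfigError` listing every offending
    field path. Applied defaults (e.g. a missing discount rate resolving to
    0.03) are echoed to the log.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    try:
        config = RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"invalid configuration {path}:\n{exc}") from exc

    baseline_raw = raw.get("baseline", {})
    if "discount_rate" not in baseline_raw:
        logger.info("discount_rate not given; default %.2f applied", 0.03)
    logger.info(
        "loaded config %r: variant=%s seed=%d cohort=%d replications=%d",
        config.label,
        config.variant,
        config.seed,
        config.cohort_size,
        config.n_replications,
    )
    return config
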