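"""End-to-end orchestration: simulation → costing → outcomes → ICER matrix.

:func:`run_pipeline` executes a validated :class:`~anc_cea.config.RunConfig`
and returns a :class:`ReportBundle` holding the national-cost table, the
health-gains table, the ICER matrix with classifications, and a manifest
echoing every input parameter (auditability: re-running from the manifest
reproduces every output byte-for-byte for a fixed seed).
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attendance import (
    CostSimulationResult,
    relative_spread_check,
    simulate_cost_distribution,
)
from .config import RunConfig
from .elicitation import (
    OutcomeScenario,
    build_outcome_scenarios,
    merge_delphi_rounds,
    read_expert_csv,
)
from .engine import CEAResult, build_cea_table
from .outcomes import HealthGains, health_gains, maternal_years_per_death

logger = logging.getLogger(__name__)

__all__ = ["ReportBundle", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ReportBundle:
    """All artefacts of one pipeline run."""

    config: RunConfig
    cost_results: dict[str, CostSimulationResult]
    outcome_scenarios: list[OutcomeScenario]
    gains: dict[str, HealthGains]
    cea_results: list[CEAResult]
    cost_table: pd.DataFrame
    gains_table: pd.DataFrame
    icer_table: pd.DataFrame
    manifest: dict
    summary: str = ""

    def percent_increase(self, scenario_label: str) -> int:
        """Cost increase of a scenario over current practice, whole percent."""
        row = self.cost_table.loc[self.cost_table["scenario"] == scenario_label]
        if row.empty:
            raise KeyError(f"no costing scenario {scenario_label!r}")
        return int(row["pct_increase"].iloc[0])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write CSV tables, machine-readable JSON and the manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["cost_table"] = out / "cost_table.csv"
        self.cost_table.to_csv(paths["cost_table"], index=False)
        paths["gains_table"] = out / "health_gains.csv"
        self.gains_table.to_csv(paths["gains_table"], index=False)
        paths["icer_table"] = out / "icer_table.csv"
        self.icer_table.to_csv(paths["icer_table"])

        results = {
            "cost": {k: v.to_dict() for k, v in self.cost_results.items()},
            "gains": {k: v.to_dict() for k, v in self.gains.items()},
            "cea": [r.to_dict() for r in self.cea_results],
        }
        paths["results"] = out / "results.json"
        with open(paths["results"], "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")

        paths["manifest"] = out / "manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

        paths["summary"] = out / "summary.txt"
        paths["summary"].write_text(self.summary)

        per_rep = pd.concat(
            [
                pd.DataFrame(
                    {
                        "scenario": label,
                        "replication": np.arange(1, r.n_replications + 1),
                        "total_cost": r.total_cost_per_replication,
                    }
                )
                for label, r in self.cost_results.items()
            ],
            ignore_index=True,
        )
        paths["replications"] = out / "replication_totals.csv"
        per_rep.to_csv(paths["replications"], index=False)
        return paths


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("simulate-costs")
def _simulate_costs(config: RunConfig) -> dict[str, CostSimulationResult]:
    schedules = config.schedule_map()
    scenarios = config.attendance_scenarios
    # one independent sub-seed per scenario, derived from the master seed
    sub_seeds = (
        np.random.SeedSequence(config.seed).generate_state(len(scenarios)) % 2**31
    )
    results = {}
    for spec, sub_seed in zip(scenarios, sub_seeds):
        result = simulate_cost_distribution(
            schedules[spec.schedule],
            spec.to_domain(),
            cohort_size=config.cohort_size,
            n_replications=config.n_replications,
            seed=int(sub_seed),
        )
        if not spec.degenerate:
            ok, spread = relative_spread_check(result)
            logger.info(
                "scenario %s: replication spread %.5f%% (%s)",
                spec.label,
                100 * spread,
                "reliable" if ok else "UNRELIABLE",
            )
        results[spec.label] = result
    return results


@_stage("outcomes")
def _outcome_scenarios(config: RunConfig) -> list[OutcomeScenario]:
    spec = config.outcomes
    if spec.source == "expert_csv":
        responses = read_expert_csv(spec.expert_csv)
        final = merge_delphi_rounds(responses)
        pess, opt = build_outcome_scenarios(final)
        return [pess, opt]
    return [
        OutcomeScenario(s.label, s.perinatal_reduction_pct, s.maternal_reduction_pct)
        for s in spec.scenarios
    ]


def _cost_table(
    config: RunConfig, cost_results: dict[str, CostSimulationResult]
) -> pd.DataFrame:
    cea = config.cea
    rows = [
        {
            "scenario": "current-practice",
            "cost_per_woman_mean": cea.comparator_cost_per_woman_usd,
            "cost_per_woman_sd": float("nan"),
            "total_mean": cea.comparator_total_cost_usd,
            "total_min": float("nan"),
            "total_max": float("nan"),
            "incremental_per_woman": 0.0,
            "incremental_total": 0.0,
            "pct_increase": 0,
        }
    ]
    for spec in config.attendance_scenarios:
        r = cost_results[spec.label]
        delta_total = r.mean_total - cea.comparator_total_cost_usd
        rows.append(
            {
                "scenario": spec.label,
                "cost_per_woman_mean": r.mean_cost_per_woman,
                "cost_per_woman_sd": r.sd_cost_per_woman,
                "total_mean": r.mean_total,
                "total_min": r.min_total,
                "total_max": r.max_total,
                "incremental_per_woman": r.mean_cost_per_woman
                - cea.comparator_cost_per_woman_usd,
                "incremental_total": delta_total,
                "pct_increase": _round_half_up(
                    100.0 * delta_total / cea.comparator_total_cost_usd
                ),
            }
        )
    return pd.DataFrame(rows)


def _gains_table(gains: dict[str, HealthGains], config: RunConfig) -> pd.DataFrame:
    rows = []
    for g in gains.values():
        rows.append(
            {
                "outcome_scenario": g.scenario_label,
                "perinatal_deaths_averted": g.perinatal_deaths_averted,
                "maternal_deaths_averted": g.maternal_deaths_averted,
                "perinatal_lys": round(g.perinatal_lys),
                "maternal_lys": round(g.maternal_lys),
                "total_lys": round(g.total_lys),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Stages: attendance/cost simulation for every scenario, outcome-scenario
    resolution (explicit values or expert-panel CSV), deaths averted and
    discounted life-years saved, and the costing x outcome ICER matrix.
    Any stage error aborts with the stage name and cause.
    """
    cost_results = _simulate_costs(config)
    scenarios = _outcome_scenarios(config)

    baseline = config.baseline_domain()
    gains = {s.label: health_gains(baseline, s) for s in scenarios}

    cea_inputs = {
        spec.label: cost_results[spec.label]
        for spec in config.attendance_scenarios
        if spec.include_in_cea
    }
    cea_config = config.cea_domain()
    if cea_inputs:
        try:
            cea_results = build_cea_table(cea_inputs, gains, cea_config)
        except Exception as exc:
            raise PipelineError(f"stage 'cea' failed: {exc}") from exc
    else:
        # costing-only run (e.g. full utilisation of the current policy):
        # no ICER matrix to build
        cea_results = []

    cost_table = _cost_table(config, cost_results)
    gains_table = _gains_table(gains, config)
    if cea_results:
        icer_table = pd.DataFrame(
            [
                {
                    "costing_scenario": r.costing_scenario,
                    "outcome_scenario": r.outcome_scenario,
                    "icer": r.icer_rounded,
                }
                for r in cea_results
            ]
        ).pivot(index="costing_scenario", columns="outcome_scenario", values="icer")
    else:
        icer_table = pd.DataFrame(
            index=pd.Index([], name="costing_scenario"),
            columns=pd.Index([], name="outcome_scenario"),
        )

    manifest = {
        "package_version": __version__,
        "config": config.model_dump(mode="json"),
        "perinatal_discount_horizon_years": config.perinatal_horizon_years,
        "maternal_years_per_death": maternal_years_per_death(baseline),
        "replication_spread": {
            k: v.relative_spread for k, v in cost_results.items()
        },
    }

    lines = [
        f"run {config.label!r} (variant={config.variant}, seed={config.seed}, "
        f"cohort={config.cohort_size}, replications={config.n_replications})",
        "",
        "National cost (USD):",
        cost_table.round(2).to_string(index=False),
        "",
        "Health gains (discounted life-years saved):",
        gains_table.to_string(index=False),
        "",
        "Incremental cost per life-year saved (USD, rounded):",
        icer_table.to_string(),
        "",
        "Classification:",
    ]
    for r in cea_results:
        lines.append(
            f"  {r.costing_scenario} x {r.outcome_scenario}: "
            f"${r.icer_rounded}/LYS -> {r.classification}"
        )
    summary = "\n".join(lines) + "\n"

    return ReportBundle(
        config=config,
        cost_results=cost_results,
        outcome_scenarios=scenarios,
        gains=gains,
        cea_results=cea_results,
        cost_table=cost_table,
        gains_table=gains_table,
        icer_table=icer_table,
        manifest=manifest,
        summary=summary,
    )
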