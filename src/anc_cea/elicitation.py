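"""Two-round Delphi expert elicitation for mortality-reduction scenarios.

Eight practising gynaecologists/obstetricians were asked how much an
eight-contact antenatal-care policy would reduce perinatal and maternal
mortality, then shown the anonymized group response and allowed to revise.
This module merges the two rounds (round-2 values supersede; non-response
confirms round 1), and builds an optimistic and a pessimistic outcome
scenario per indicator by sorting the final estimates and taking the mean
of each half.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ExpertResponse",
    "OutcomeScenario",
    "merge_delphi_rounds",
    "split_outcome_scenarios",
    "build_outcome_scenarios",
    "read_expert_csv",
    "write_expert_csv",
]


@dataclass(frozen=True)
class ExpertResponse:
    """One expert's estimates in one elicitation round.

    Reductions are stored as positive percentages; the direction (a
    mortality *decrease*) is applied at reporting time.
    """

    expert_id: str
    round: int
    perinatal_reduction_pct: float
    maternal_reduction_pct: float

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise ValueError(f"round must be 1 or 2, got {self.round}")
        for name in ("perinatal_reduction_pct", "maternal_reduction_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class OutcomeScenario:
    """A paired perinatal/maternal mortality-reduction scenario."""

    label: str
    perinatal_reduction_pct: float
    maternal_reduction_pct: float


def merge_delphi_rounds(
    responses: Iterable[ExpertResponse],
) -> dict[str, tuple[float, float]]:
    """Collapse two elicitation rounds to one final estimate pair per expert.

    Round-2 values are retained where present; an expert who did not respond
    in round 2 is taken to confirm their round-1 estimates. Returns
    ``{expert_id: (perinatal_pct, maternal_pct)}``.

    Raises ``ValueError`` on duplicate (expert, round) entries or a round-2
    response with no matching round-1 response.
    """
    by_expert: dict[str, dict[int, ExpertResponse]] = {}
    for r in responses:
        rounds = by_expert.setdefault(r.expert_id, {})
        if r.round in rounds:
            raise ValueError(
                f"duplicate response for expert {r.expert_id!r} round {r.round}"
            )
        rounds[r.round] = r

    final: dict[str, tuple[float, float]] = {}
    for expert_id, rounds in by_expert.items():
        if 2 in rounds and 1 not in rounds:
            raise ValueError(
                f"expert {expert_id!r} has a round-2 response without round 1"
            )
        chosen = rounds.get(2, rounds[1])
        final[expert_id] = (
            chosen.perinatal_reduction_pct,
            chosen.maternal_reduction_pct,
        )
    return final


def split_outcome_scenarios(values: Sequence[float]) -> tuple[float, float]:
    """Half-split aggregation for one indicator.

    Sorts the final estimates ascending and divides them into two
    sub-groups; the lower-half mean is the pessimistic parameter and the
    upper-half mean the optimistic one. For an odd count the middle value
    joins the lower (pessimistic) half — the conservative choice.
    """
    vals = sorted(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError("half-split requires at least 2 values")
    cut = (len(vals) + 1) // 2  # middle value joins the lower half
    lower, upper = vals[:cut], vals[cut:]
    return sum(lower) / len(lower), sum(upper) / len(upper)


def build_outcome_scenarios(
    final_estimates: Mapping[str, tuple[float, float]],
) -> tuple[OutcomeScenario, OutcomeScenario]:
    """Build (pessimistic, optimistic) scenarios from merged estimates.

    The perinatal and maternal indicators are split independently: an expert
    may fall in the lower half for one indicator and the upper half for the
    other.
    """
    if len(final_estimates) < 2:
        raise ValueError("scenario construction requires at least 2 experts")
    perinatal = [p for p, _ in final_estimates.values()]
    maternal = [m for _, m in final_estimates.values()]
    peri_pess, peri_opt = split_outcome_scenarios(perinatal)
    mat_pess, mat_opt = split_outcome_scenarios(maternal)
    return (
        OutcomeScenario("pessimistic", peri_pess, mat_pess),
        OutcomeScenario("optimistic", peri_opt, mat_opt),
    )


_CSV_FIELDS = ["expert_id", "round", "perinatal_reduction_pct", "maternal_reduction_pct"]


def read_expert_csv(path: str | Path) -> list[ExpertResponse]:
    """Read expert responses from a CSV with columns
    expert_id, round, perinatal_reduction_pct, maternal_reduction_pct."""
    responses = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"expert CSV missing columns: {sorted(missing)}")
        for row in reader:
            responses.append(
                ExpertResponse(
                    expert_id=row["expert_id"],
                    round=int(row["round"]),
                    perinatal_reduction_pct=float(row["perinatal_reduction_pct"]),
                    maternal_reduction_pct=float(row["maternal_reduction_pct"]),
                )
            )
    return responses


def write_expert_csv(responses: Iterable[ExpertResponse], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for r in responses:
            writer.writerow(
                [r.expert_id, r.round, r.perinatal_reduction_pct, r.maternal_reduction_pct]
            )
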