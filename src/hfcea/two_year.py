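"""Two-year extension: year-1 survivors re-enter an identical tree.

Survivors of year 1 face the same chance structure again in year 2,
undiscounted, with three levers that may differ from year 1 per the
scenario grid: the intervention's adherence gain, the good-adherence
exacerbation probability, and the subsequent-year intervention cost
(base $400).  Survivors who ended year 1 worsened carry the worsened
utility as their alive-state utility through year 2 but face the same
transition probabilities as everyone else.  Year-2 adherence status is
re-drawn from the arm-level adherence probabilities by default; a
persistence switch instead carries each survivor's year-1 status
forward.  Eight named scenarios cover the high/low assumption grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import pandas as pd

from .cost_model import ResourceUseSchedule, calibrate_schedule
from .parameters import ParameterSet, intervention_adherence
from .tree_model import (
    Arm,
    TimingAssumptions,
    UtilitySet,
    enumerate_paths,
    evaluate_arm,
    make_arms,
    path_qaly,
)
from .cost_model import path_cost

__all__ = [
    "TwoYearScenario",
    "TwoYearResult",
    "SCENARIOS",
    "evaluate_two_year",
    "two_year_table",
]

#: label -> (gain_y2, p_exac_good_y2, intervention_cost_y2) assumption levels
SCENARIO_GRID: dict[str, tuple[str, str, str]] = {
    "same": ("base", "base", "base"),
    "more-effective": ("upper", "base", "base"),
    "less-expensive": ("base", "base", "lower"),
    "more-effective-less-expensive": ("upper", "base", "lower"),
    "less-effective": ("lower", "base", "base"),
    "more-expensive": ("base", "base", "upper"),
    "more-effective-lower-risk": ("upper", "lower", "base"),
    "higher-risk": ("base", "upper", "base"),
}


@dataclass(frozen=True)
class TwoYearScenario:
    label: str
    gain_y2: str = "base"  # base | upper | lower
    p_exac_good_y2: str = "base"
    intervention_cost_y2: str = "base"

    def __post_init__(self):
        for lever in (self.gain_y2, self.p_exac_good_y2, self.intervention_cost_y2):
            if lever not in ("base", "upper", "lower"):
                raise ValueError(f"assumption level must be base/upper/lower, got {lever!r}")


SCENARIOS: dict[str, TwoYearScenario] = {
    label: TwoYearScenario(label, *levels) for label, levels in SCENARIO_GRID.items()
}


@dataclass(frozen=True)
class TwoYearResult:
    label: str
    delta_cost_2y: float
    delta_qaly_2y: float
    dominant: bool
    delta_cost_1y: float
    delta_qaly_1y: float


def _bound(params: ParameterSet, name: str, level: str) -> float:
    spec = params.spec(name)
    return {"base": spec.base, "upper": spec.high, "lower": spec.low}[level]


def _arm_two_year_totals(
    arm: Arm,
    arm_y2_p_good,  # float, or dict {"good": p, "poor": p} under persistence
    intervention_cost_y2: float,
    values_y1: Mapping[str, float],
    values_y2: Mapping[str, float],
    schedule_y1: ResourceUseSchedule,
    schedule_y2: ResourceUseSchedule,
    utilities_y2: Optional[UtilitySet],
    timing: TimingAssumptions,
    persistence: bool,
) -> tuple[float, float, float]:
    """(total cost, total QALYs, survivor mass) for one arm over two years."""
    utilities_y1 = UtilitySet.from_values(values_y1)
    total_q = total_c = 0.0
    # survivor mass entering year 2, keyed by (adherence, worsened?)
    mass: dict[tuple[str, bool], float] = {}
    for path, prob in enumerate_paths(arm, values_y1):
        total_q += prob * path_qaly(path, utilities_y1, timing)
        total_c += prob * path_cost(path, schedule_y1, arm)
        if path.survive:
            key = (path.adherence, path.post_state == "worsened")
            mass[key] = mass.get(key, 0.0) + prob
    survivor_mass = sum(mass.values())

    base_u = utilities_y2 or UtilitySet.from_values(values_y2)
    # year-2 per-entrant expectations, by worsened status (and adherence
    # group under persistence); intervention cost is charged per entrant
    for (adherence, worsened), m in mass.items():
        if persistence:
            p_good = 1.0 if adherence == "good" else 0.0
        else:
            p_good = arm_y2_p_good
        arm_y2 = Arm(arm.label, p_good, intervention_cost_y2 if arm.label == "intervention" else 0.0)
        u = base_u if not worsened else UtilitySet(
            base_u.u_exacerbation, base_u.u_worsened, base_u.u_worsened
        )
        res = evaluate_arm(arm_y2, values_y2, timing, schedule_y2, u)
        total_q += m * res.expected_qaly
        total_c += m * res.expected_cost
    return total_c, total_q, survivor_mass


def evaluate_two_year(
    scenario: Union[TwoYearScenario, str],
    params: ParameterSet,
    schedule: Optional[ResourceUseSchedule] = None,
    timing: TimingAssumptions = TimingAssumptions(),
    persistence: bool = False,
    y2_utilities: Optional[UtilitySet] = None,
    y2_schedule: Optional[ResourceUseSchedule] = None,
    y2_intervention_cost: Optional[float] = None,
    y2_values: Optional[Mapping[str, float]] = None,
) -> TwoYearResult:
    """Evaluate one two-year scenario (year-1 base case + scenario year 2).

    The ``y2_*`` overrides exist for diagnostics (e.g. a zeroed year 2
    collapses the result onto the one-year model exactly).
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise KeyError(
                f"unknown two-year scenario {scenario!r}; "
                f"bundled: {', '.join(SCENARIOS)}"
            ) from None
    schedule = schedule if schedule is not None else calibrate_schedule(params)
    schedule_y2 = y2_schedule if y2_schedule is not None else schedule

    values = params.base_values()
    values_y2 = dict(y2_values if y2_values is not None else values)
    values_y2["p_exac_good"] = _bound(params, "p_exac_good", scenario.p_exac_good_y2)
    gain_y2 = _bound(params, "adherence_gain", scenario.gain_y2)
    cost_y2 = (
        y2_intervention_cost
        if y2_intervention_cost is not None
        else _bound(params, "cost_intervention_subsequent", scenario.intervention_cost_y2)
    )

    intervention, usual = make_arms(values)
    p_good_int_y2 = intervention_adherence(values["p_good_adherence_usual"], gain_y2)

    c_i, q_i, surv_i = _arm_two_year_totals(
        intervention, p_good_int_y2, cost_y2, values, values_y2,
        schedule, schedule_y2, y2_utilities, timing, persistence,
    )
    c_u, q_u, surv_u = _arm_two_year_totals(
        usual, usual.p_good_adherence, 0.0, values, values_y2,
        schedule, schedule_y2, y2_utilities, timing, persistence,
    )

    # one-year deltas for reference
    res_i1 = evaluate_arm(intervention, values, timing, schedule)
    res_u1 = evaluate_arm(usual, values, timing, schedule)

    dc, dq = c_i - c_u, q_i - q_u
    return TwoYearResult(
        label=scenario.label,
        delta_cost_2y=dc,
        delta_qaly_2y=dq,
        dominant=(dc < 0 and dq > 0),
        delta_cost_1y=res_i1.expected_cost - res_u1.expected_cost,
        delta_qaly_1y=res_i1.expected_qaly - res_u1.expected_qaly,
    )


def survivor_mass(arm: Arm, values: Mapping[str, float]) -> float:
    """Probability of surviving year 1 (mass entering year 2)."""
    return sum(p for path, p in enumerate_paths(arm, values) if path.survive)


def two_year_table(
    params: ParameterSet,
    schedule: Optional[ResourceUseSchedule] = None,
    timing: TimingAssumptions = TimingAssumptions(),
    persistence: bool = False,
) -> pd.DataFrame:
    """All eight bundled scenarios, one row each."""
    schedule = schedule if schedule is not None else calibrate_schedule(params)
    rows = []
    for label in SCENARIOS:
        r = evaluate_two_year(label, params, schedule, timing, persistence)
        rows.append(
            {
                "scenario": label,
                "delta_cost_2y": r.delta_cost_2y,
                "delta_qaly_2y": r.delta_qaly_2y,
                "dominant": r.dominant,
                "delta_cost_1y": r.delta_cost_1y,
                "delta_qaly_1y": r.delta_qaly_1y,
            }
        )
    return pd.DataFrame(rows)
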