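"""The one-year decision tree: paths, QALYs, arm expectations, and the
incremental comparison.

Structure.  A cohort of 75-year-olds with heart failure and cognitive
impairment chooses (decision node) between a pictorial medication sheet
and usual care.  Chance nodes then split each arm by adherence status
(good vs poor at the 80% pill-count cutoff), heart-failure exacerbation
(hospitalized decompensation), survival, and — for exacerbation
survivors — worsening versus recovery, giving 10 terminal paths per arm.

Timing conventions.  Decedents die mid-year and accrue half a year of
utility; an exacerbation lasts one month at the exacerbation utility,
with the remaining eleven months at the destination state's utility.
Under the default decedent convention all deaths accrue their half year
at the stable-HF utility; the alternatives (exacerbation month first) are
selectable via :class:`TimingAssumptions`.  Nothing is discounted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .parameters import ParameterSet, intervention_adherence

__all__ = [
    "Arm",
    "TreePath",
    "TimingAssumptions",
    "UtilitySet",
    "ArmResult",
    "CEComparison",
    "PATHS",
    "make_arms",
    "enumerate_paths",
    "path_qaly",
    "evaluate_arm",
    "compare",
    "scale_to_population",
    "path_table",
]

Values = Union[ParameterSet, Mapping[str, float]]


@dataclass(frozen=True)
class Arm:
    label: str  # intervention | usual_care
    p_good_adherence: float
    intervention_cost_year1: float = 0.0

    def __post_init__(self):
        if self.label == "usual_care" and self.intervention_cost_year1 != 0.0:
            raise ValueError("usual care carries no intervention cost")
        if not (0.0 <= self.p_good_adherence <= 1.0):
            raise ValueError(f"p_good_adherence out of [0, 1]: {self.p_good_adherence}")


def make_arms(values: Values) -> tuple[Arm, Arm]:
    """Build the (intervention, usual-care) arm pair from parameter values."""
    p_usual = values["p_good_adherence_usual"]
    p_int = intervention_adherence(p_usual, values["adherence_gain"])
    intervention = Arm("intervention", p_int, values["cost_intervention_year1"])
    usual = Arm("usual_care", p_usual, 0.0)
    return intervention, usual


@dataclass(frozen=True)
class TreePath:
    """One terminal trajectory through the tree."""

    adherence: str  # good | poor
    exacerbation: bool
    survive: bool
    post_state: str  # worsened | recovered_stable | stable | dead

    def __post_init__(self):
        ok = (
            (self.exacerbation and not self.survive and self.post_state == "dead")
            or (self.exacerbation and self.survive and self.post_state in ("worsened", "recovered_stable"))
            or (not self.exacerbation and self.survive and self.post_state == "stable")
            or (not self.exacerbation and not self.survive and self.post_state == "dead")
        )
        if not ok:
            raise ValueError(f"invalid path: {self!r}")

    @property
    def path_id(self) -> str:
        mid = "exac" if self.exacerbation else "no_exac"
        end = self.post_state if self.survive else "die"
        return f"{self.adherence}/{mid}/{end}"


def _subtree(adherence: str) -> list[TreePath]:
    return [
        TreePath(adherence, True, False, "dead"),
        TreePath(adherence, True, True, "worsened"),
        TreePath(adherence, True, True, "recovered_stable"),
        TreePath(adherence, False, True, "stable"),
        TreePath(adherence, False, False, "dead"),
    ]


#: the 10 valid paths (per arm), in enumeration order
PATHS: tuple[TreePath, ...] = tuple(_subtree("good") + _subtree("poor"))


@dataclass(frozen=True)
class TimingAssumptions:
    death_fraction_of_year: float = 0.5
    exac_duration_years: float = 1.0 / 12.0
    #: how decedents' alive time is valued: stable_baseline (default),
    #: exac_then_stable, or exac_then_worsened
    decedent_utility_convention: str = "stable_baseline"

    def __post_init__(self):
        if not (0.0 < self.death_fraction_of_year <= 1.0):
            raise ValueError("death_fraction_of_year must be in (0, 1]")
        if not (0.0 < self.exac_duration_years <= 1.0):
            raise ValueError("exac_duration_years must be in (0, 1]")
        if self.decedent_utility_convention not in (
            "stable_baseline",
            "exac_then_stable",
            "exac_then_worsened",
        ):
            raise ValueError(f"unknown convention {self.decedent_utility_convention!r}")


@dataclass(frozen=True)
class UtilitySet:
    u_exacerbation: float = 0.560
    u_stable: float = 0.780
    u_worsened: float = 0.600  # NYHA II-IV mean

    def __post_init__(self):
        for v in (self.u_exacerbation, self.u_stable, self.u_worsened):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"utility out of [0, 1]: {v}")

    @classmethod
    def from_values(cls, values: Values) -> "UtilitySet":
        return cls(values["u_exacerbation"], values["u_stable"], values["u_worsened"])


def _branch_probabilities(values: Values) -> dict[str, float]:
    probs = {
        "p_exac_good": values["p_exac_good"],
        "p_exac_poor": values["p_exac_poor"],
        "p_survive_exac": values["p_survive_exac"],
        "p_worsen": values["p_worsen"],
        "p_survive_no_exac": values["p_survive_no_exac"],
    }
    bad = [k for k, v in probs.items() if not (0.0 <= v <= 1.0)]
    if bad:
        raise ValueError(f"branch probabilities outside [0, 1]: {', '.join(bad)}")
    return probs


def enumerate_paths(arm: Arm, values: Values) -> list[tuple[TreePath, float]]:
    """The 10 terminal paths of an arm with their probabilities (sum to 1)."""
    b = _branch_probabilities(values)
    out: list[tuple[TreePath, float]] = []
    for path in PATHS:
        p_adh = arm.p_good_adherence if path.adherence == "good" else 1.0 - arm.p_good_adherence
        p_exac = b["p_exac_good"] if path.adherence == "good" else b["p_exac_poor"]
        if path.exacerbation:
            p = p_exac * (b["p_survive_exac"] if path.survive else 1.0 - b["p_survive_exac"])
            if path.survive:
                p *= b["p_worsen"] if path.post_state == "worsened" else 1.0 - b["p_worsen"]
        else:
            p = (1.0 - p_exac) * (
                b["p_survive_no_exac"] if path.survive else 1.0 - b["p_survive_no_exac"]
            )
        out.append((path, p_adh * p))
    return out


def path_qaly(path: TreePath, utilities: UtilitySet, timing: TimingAssumptions = TimingAssumptions()) -> float:
    """QALYs accrued along one path over the modelled year."""
    u, t = utilities, timing
    if path.survive:
        if path.exacerbation:
            dest = u.u_worsened if path.post_state == "worsened" else u.u_stable
            return t.exac_duration_years * u.u_exacerbation + (1.0 - t.exac_duration_years) * dest
        return u.u_stable
    # decedent: half a year alive, valued per the selected convention
    if path.exacerbation and t.decedent_utility_convention != "stable_baseline":
        rest = u.u_stable if t.decedent_utility_convention == "exac_then_stable" else u.u_worsened
        exac_time = min(t.exac_duration_years, t.death_fraction_of_year)
        return exac_time * u.u_exacerbation + (t.death_fraction_of_year - exac_time) * rest
    return t.death_fraction_of_year * u.u_stable


@dataclass(frozen=True)
class ArmResult:
    label: str
    expected_cost: float
    expected_qaly: float


def evaluate_arm(
    arm: Arm,
    values: Values,
    timing: TimingAssumptions = TimingAssumptions(),
    schedule=None,
    utilities: Optional[UtilitySet] = None,
) -> ArmResult:
    """Probability-weighted cost and QALY expectation for one arm.

    ``schedule`` is a :class:`~hfcea.cost_model.ResourceUseSchedule`; if
    omitted, costs are reported as 0 plus the arm's intervention cost.
    """
    from .cost_model import path_cost  # local import to avoid a cycle

    utilities = utilities or UtilitySet.from_values(values)
    total_q = total_c = 0.0
    for path, prob in enumerate_paths(arm, values):
        total_q += prob * path_qaly(path, utilities, timing)
        if schedule is not None:
            total_c += prob * path_cost(path, schedule, arm)
        else:
            total_c += prob * arm.intervention_cost_year1
    return ArmResult(arm.label, total_c, total_q)


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison on the cost-effectiveness plane.

    Deltas are intervention minus usual care; the plane puts dQALY on the
    horizontal axis and dcost on the vertical, so the dominant quadrant
    (more effective, less costly) is the lower right, labelled SE.
    """

    cost_per_arm: tuple[float, float]  # (intervention, usual_care)
    qaly_per_arm: tuple[float, float]
    delta_cost: float
    delta_qaly: float
    quadrant: str  # NE | NW | SE | SW
    dominant: bool
    icer: Optional[float]
    cost_effective: bool
    wtp: float
    boundary_note: str = ""

    def to_dict(self) -> dict:
        return {
            "cost_intervention": self.cost_per_arm[0],
            "cost_usual_care": self.cost_per_arm[1],
            "qaly_intervention": self.qaly_per_arm[0],
            "qaly_usual_care": self.qaly_per_arm[1],
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "quadrant": self.quadrant,
            "dominant": self.dominant,
            "icer": self.icer,
            "cost_effective": self.cost_effective,
            "wtp": self.wtp,
            "boundary_note": self.boundary_note,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _classify_quadrant(delta_qaly: float, delta_cost: float) -> tuple[str, str]:
    """Quadrant label plus a note when a delta sits exactly on an axis.

    Axis cases are assigned to the adjacent non-dominant quadrant, so a
    strictly-interior SE point is the only way to be flagged dominant.
    """
    if delta_qaly > 0 and delta_cost < 0:
        return "SE", ""
    if delta_qaly == 0 or delta_cost == 0:
        note = "on-axis sample assigned to adjacent non-dominant quadrant"
        if delta_qaly == 0:
            return ("NE" if delta_cost == 0 else "NW" if delta_cost > 0 else "SW"), note
        return ("NE" if delta_qaly > 0 else "SW"), note
    if delta_cost > 0:
        return ("NE" if delta_qaly > 0 else "NW"), ""
    return "SW", ""  # delta_qaly < 0, delta_cost < 0


def compare(
    intervention_result: ArmResult,
    usual_result: ArmResult,
    wtp: float = 150_000.0,
) -> CEComparison:
    """Incremental cost, incremental QALYs, quadrant, dominance, and ICER."""
    dc = intervention_result.expected_cost - usual_result.expected_cost
    dq = intervention_result.expected_qaly - usual_result.expected_qaly
    quadrant, note = _classify_quadrant(dq, dc)
    dominant = dc < 0 and dq > 0
    # ICER only where cost and effect trade off (NE) or both fall (SW)
    icer = dc / dq if (quadrant in ("NE", "SW") and dq != 0) else None
    if dq == 0 and dc != 0:
        note = "cost-dominant (saves money, equal QALYs)" if dc < 0 else "dominated on cost alone"
    cost_effective = dominant or (quadrant == "NE" and icer is not None and icer <= wtp)
    return CEComparison(
        cost_per_arm=(intervention_result.expected_cost, usual_result.expected_cost),
        qaly_per_arm=(intervention_result.expected_qaly, usual_result.expected_qaly),
        delta_cost=dc,
        delta_qaly=dq,
        quadrant=quadrant,
        dominant=dominant,
        icer=icer,
        cost_effective=cost_effective,
        wtp=wtp,
        boundary_note=note,
    )


def scale_to_population(ce: CEComparison, n: int) -> tuple[float, float]:
    """(QALYs gained, dollars saved) for a program covering ``n`` patients."""
    if n < 0:
        raise ValueError("population size must be non-negative")
    return n * ce.delta_qaly, n * (-ce.delta_cost)


def path_table(
    arm: Arm,
    values: Values,
    timing: TimingAssumptions = TimingAssumptions(),
    schedule=None,
    utilities: Optional[UtilitySet] = None,
) -> pd.DataFrame:
    """Per-path table (id, probability, QALY, cost) for reporting."""
    from .cost_model import path_cost

    utilities = utilities or UtilitySet.from_values(values)
    rows = []
    for path, prob in enumerate_paths(arm, values):
        rows.append(
            {
                "arm": arm.label,
                "path_id": path.path_id,
                "probability": prob,
                "qaly": path_qaly(path, utilities, timing),
                "cost": path_cost(path, schedule, arm) if schedule is not None else arm.intervention_cost_year1,
            }
        )
    return pd.DataFrame(rows)
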