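"""One-way deterministic sensitivity, scenario analysis, and Monte Carlo
probabilistic sensitivity analysis (PSA) on the one-year model.

All three work through one evaluation pipeline
(:func:`evaluate_values`): given a full set of parameter values, rebuild
the arms (intervention adherence = usual care + gain, capped at 1), the
utility set, and the cost schedule (calibrated aggregates perturbed
proportionally to the sampled cost parameters), then evaluate both arms
and compare.  Derived quantities are always recomputed from the
primitives in play, so one-way runs differ from base in exactly one
primitive and PSA draws stay internally coherent.

PSA samples every tabulated parameter independently from its fitted
beta/gamma distribution (no correlation structure is published).  Both
exacerbation probabilities are drawn from their own distributions by
default; ``hr_link=True`` instead derives the poor-adherence probability
from the good-adherence draw via the hazard ratio.  One master seed
spawns a deterministic substream per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .cost_model import ResourceUseSchedule, calibrate_schedule, scale_schedule
from .parameters import ParameterSet, intervention_adherence
from .tree_model import (
    CEComparison,
    TimingAssumptions,
    UtilitySet,
    compare,
    evaluate_arm,
    make_arms,
)

__all__ = [
    "OneWayResult",
    "PSAResult",
    "ScenarioSpec",
    "BUNDLED_SCENARIOS",
    "evaluate_values",
    "base_case",
    "one_way",
    "tornado",
    "run_psa",
    "run_scenario",
]

logger = logging.getLogger(__name__)


def evaluate_values(
    values: Mapping[str, float],
    base_values: Mapping[str, float],
    schedule: ResourceUseSchedule,
    timing: TimingAssumptions = TimingAssumptions(),
    wtp: float = 150_000.0,
) -> CEComparison:
    """Evaluate both arms under a (possibly perturbed) value set and compare."""
    intervention, usual = make_arms(values)
    utilities = UtilitySet.from_values(values)
    sched = scale_schedule(schedule, values, base_values)
    res_i = evaluate_arm(intervention, values, timing, sched, utilities)
    res_u = evaluate_arm(usual, values, timing, sched, utilities)
    return compare(res_i, res_u, wtp=wtp)


def base_case(
    params: ParameterSet,
    schedule: Optional[ResourceUseSchedule] = None,
    timing: TimingAssumptions = TimingAssumptions(),
    wtp: Optional[float] = None,
) -> CEComparison:
    """Base-case comparison with the calibrated (or supplied) schedule."""
    schedule = schedule if schedule is not None else calibrate_schedule(params)
    wtp = wtp if wtp is not None else params["wtp_threshold"]
    base = params.base_values()
    return evaluate_values(base, base, schedule, timing, wtp)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    base: tuple[float, float]  # (delta_cost, delta_qaly)
    at_low: tuple[float, float]
    at_high: tuple[float, float]


def one_way(
    parameter: str,
    params: ParameterSet,
    schedule: Optional[ResourceUseSchedule] = None,
    timing: TimingAssumptions = TimingAssumptions(),
    wtp: Optional[float] = None,
) -> OneWayResult:
    """Re-evaluate the full model at one parameter's low and high bounds."""
    if parameter not in params.specs:
        raise KeyError(f"unknown parameter: {parameter}")
    schedule = schedule if schedule is not None else calibrate_schedule(params)
    wtp = wtp if wtp is not None else params["wtp_threshold"]
    spec = params.spec(parameter)
    base_vals = params.base_values()

    def deltas(value: float) -> tuple[float, float]:
        vals = dict(base_vals)
        vals[parameter] = value
        ce = evaluate_values(vals, base_vals, schedule, timing, wtp)
        return ce.delta_cost, ce.delta_qaly

    return OneWayResult(
        parameter=parameter,
        base=deltas(spec.base),
        at_low=deltas(spec.low),
        at_high=deltas(spec.high),
    )


def tornado(
    params: ParameterSet,
    schedule: Optional[ResourceUseSchedule] = None,
    timing: TimingAssumptions = TimingAssumptions(),
) -> pd.DataFrame:
    """One-way results for every tabulated parameter, one row each."""
    schedule = schedule if schedule is not None else calibrate_schedule(params)
    rows = []
    for name in params.specs:
        r = one_way(name, params, schedule, timing)
        rows.append(
            {
                "parameter": name,
                "delta_cost_base": r.base[0],
                "delta_qaly_base": r.base[1],
                "delta_cost_low": r.at_low[0],
                "delta_qaly_low": r.at_low[1],
                "delta_cost_high": r.at_high[0],
                "delta_qaly_high": r.at_high[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo sample of (delta_cost, delta_qaly) pairs with summaries."""

    samples: np.ndarray  # shape (n, 2): columns delta_cost, delta_qaly
    seed: int
    wtp: float
    pct_dominant: float
    pct_cost_effective: float
    pct_quadrants: dict[str, float]
    icer_range_ne_quadrant: Optional[tuple[float, float]]
    n_clamped: int = 0

    @property
    def n(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["delta_cost", "delta_qaly"])

    def summary(self) -> dict:
        dc, dq = self.samples[:, 0], self.samples[:, 1]
        return {
            "n_iterations": self.n,
            "seed": self.seed,
            "wtp": self.wtp,
            "pct_dominant": self.pct_dominant,
            "pct_cost_effective": self.pct_cost_effective,
            "pct_quadrants": self.pct_quadrants,
            "icer_range_ne_quadrant": self.icer_range_ne_quadrant,
            "delta_cost_range": [float(dc.min()), float(dc.max())],
            "delta_qaly_range": [float(dq.min()), float(dq.max())],
            "n_clamped": self.n_clamped,
        }


def _draw_values(
    dists: Mapping, order: list[str], rng: np.random.Generator, hr: float, hr_link: bool
) -> tuple[dict[str, float], int]:
    values = {name: float(dists[name].sample(rng)) for name in order}
    clamped = 0
    if hr_link:
        derived = values["p_exac_good"] * hr
        if derived > 1.0:
            clamped += 1
        values["p_exac_poor"] = min(derived, 1.0)
    return values, clamped


def run_psa(
    params: ParameterSet,
    n: Optional[int] = None,
    seed: int = 0,
    schedule: Optional[ResourceUseSchedule] = None,
    timing: TimingAssumptions = TimingAssumptions(),
    wtp: Optional[float] = None,
    hr_link: bool = False,
    point_mass: bool = False,
) -> PSAResult:
    """Monte Carlo PSA: sample, re-derive, re-evaluate, summarize.

    ``point_mass=True`` degenerates every distribution to its base value
    (every iteration then reproduces the base case exactly).
    """
    n = int(n if n is not None else params["n_psa_iterations"])
    if n < 1:
        raise ValueError("n must be >= 1")
    schedule = schedule if schedule is not None else calibrate_schedule(params)
    wtp = wtp if wtp is not None else params["wtp_threshold"]
    base_vals = params.base_values()
    if point_mass:
        from .parameters import FittedDistribution

        dists = {k: FittedDistribution("point_mass", v, 0.0) for k, v in base_vals.items()}
    else:
        dists = params.fitted()
    order = sorted(dists)  # fixed draw order for reproducibility
    hr = params["hazard_ratio_nonadherent"]

    streams = np.random.SeedSequence(seed).spawn(n)
    samples = np.empty((n, 2))
    dominant = np.zeros(n, dtype=bool)
    cost_effective = np.zeros(n, dtype=bool)
    quadrants = np.empty(n, dtype=object)
    icers_ne: list[float] = []
    n_clamped = 0
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        values, clamped = _draw_values(dists, order, rng, hr, hr_link)
        n_clamped += clamped
        ce = evaluate_values(values, base_vals, schedule, timing, wtp)
        samples[i] = (ce.delta_cost, ce.delta_qaly)
        dominant[i] = ce.dominant
        cost_effective[i] = ce.cost_effective
        quadrants[i] = ce.quadrant
    if n_clamped:
        logger.warning("PSA clamped %d derived probabilities to 1", n_clamped)
    icers_ne = [
        dc / dq for (dc, dq), q in zip(samples, quadrants) if q == "NE" and dq > 0
    ]
    pct_quadrants = {
        q: 100.0 * float(np.mean(quadrants == q)) for q in ("NE", "NW", "SE", "SW")
    }
    return PSAResult(
        samples=samples,
        seed=seed,
        wtp=wtp,
        pct_dominant=100.0 * float(dominant.mean()),
        pct_cost_effective=100.0 * float(cost_effective.mean()),
        pct_quadrants=pct_quadrants,
        icer_range_ne_quadrant=(min(icers_ne), max(icers_ne)) if icers_ne else None,
        n_clamped=n_clamped,
    )


# ---------------------------------------------------------------------------
# scenario analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Named program variant: per-parameter overrides of the base case.

    Each override is ``{"set": value}`` (explicit value) or
    ``{"add": delta}`` (additive change from base); supplying both for one
    parameter is a conflict.
    """

    label: str
    overrides: Mapping[str, Mapping[str, float]]

    def apply(self, base_values: Mapping[str, float]) -> dict[str, float]:
        values = dict(base_values)
        for name, override in self.overrides.items():
            if name not in values:
                raise KeyError(f"scenario {self.label!r}: unknown parameter {name!r}")
            if "set" in override and "add" in override:
                raise ValueError(
                    f"scenario {self.label!r}: conflicting overrides for {name!r}"
                )
            if "set" in override:
                values[name] = float(override["set"])
            elif "add" in override:
                values[name] = values[name] + float(override["add"])
            else:
                raise ValueError(
                    f"scenario {self.label!r}: override for {name!r} needs 'set' or 'add'"
                )
        return values


#: the three published program scenarios
BUNDLED_SCENARIOS: dict[str, ScenarioSpec] = {
    # comprehensive, well-funded rollout: upper-bound cost and adherence gain
    "richer-better": ScenarioSpec(
        "richer-better",
        {
            "cost_intervention_year1": {"set": 622.0},
            "adherence_gain": {"set": 0.278},
        },
    ),
    # reduced-price rollout with a smaller adherence gain
    "cheaper-less-effective": ScenarioSpec(
        "cheaper-less-effective",
        {
            "cost_intervention_year1": {"add": -200.05},
            "adherence_gain": {"add": -0.093},
        },
    ),
    # targeted, culturally tailored program: higher cost, lower baseline
    # adherence in the served population, same gain
    "equity-focused": ScenarioSpec(
        "equity-focused",
        {
            "cost_intervention_year1": {"add": 279.0},
            "p_good_adherence_usual": {"add": -0.139},
            "adherence_gain": {"add": 0.0},
        },
    ),
}


def run_scenario(
    spec: Union[ScenarioSpec, str],
    params: ParameterSet,
    schedule: Optional[ResourceUseSchedule] = None,
    timing: TimingAssumptions = TimingAssumptions(),
    wtp: Optional[float] = None,
) -> CEComparison:
    """Evaluate a program scenario against the calibrated base-case model."""
    if isinstance(spec, str):
        try:
            spec = BUNDLED_SCENARIOS[spec]
        except KeyError:
            raise KeyError(
                f"unknown scenario {spec!r}; bundled: {', '.join(BUNDLED_SCENARIOS)}"
            ) from None
    schedule = schedule if schedule is not None else calibrate_schedule(params)
    wtp = wtp if wtp is not None else params["wtp_threshold"]
    base_vals = params.base_values()
    values = spec.apply(base_vals)
    return evaluate_values(values, base_vals, schedule, timing, wtp)
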