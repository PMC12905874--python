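"""Model inputs: loading, validation, transforms, and probabilistic fitting.

Every quantity the decision tree consumes — clinical transition
probabilities, health-state utilities, and costs (2025 USD) — is declared
here as a :class:`ParameterSpec` with a base value, an uncertainty range,
and a distribution family, mirroring the published parameter table.
Probabilities and utilities are represented by beta distributions,
costs by gammas, both fitted by method of moments with the range read as
a central 95% interval (sigma = width / 3.92).  Derived quantities — the
poor-adherence exacerbation probability via a hazard ratio, the
intervention arm's adherence — are computed by the transform functions
below rather than stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "FittedDistribution",
    "ParameterValidationError",
    "fit_beta",
    "fit_gamma",
    "hr_to_probability",
    "intervention_adherence",
    "inflate_cost",
    "load_parameter_set",
]

#: width of a central 95% interval of a normal, in standard-deviation units
Z95_WIDTH = 3.92

BASES = ("ci95", "pct25", "pct50", "literature_range")
FAMILIES = ("beta", "gamma", "fixed")
UNITS = ("probability", "utility", "usd")

#: the 18 canonical parameter names, in table order
TABLE_NAMES = (
    "p_good_adherence_usual",
    "adherence_gain",
    "p_exac_good",
    "p_exac_poor",
    "p_survive_exac",
    "p_worsen",
    "p_survive_no_exac",
    "u_exacerbation",
    "u_stable",
    "u_worsened",
    "cost_intervention_year1",
    "cost_intervention_subsequent",
    "cost_hospitalization",
    "cost_outpatient",
    "cost_ed_visit",
    "cost_hf_medications",
    "cost_worsening_medications",
    "cost_post_acute",
)

CONSTANT_NAMES = (
    "wtp_threshold",
    "n_psa_iterations",
    "death_month",
    "exac_duration_months",
    "hazard_ratio_nonadherent",
    "cohort_age",
)


class ParameterValidationError(ValueError):
    """A parameter configuration violates the schema; names the offending keys."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: base value, uncertainty range, and distribution family."""

    name: str
    base: float
    low: float
    high: float
    basis: str
    family: str
    units: str

    def validate(self) -> None:
        errs = []
        if self.basis not in BASES:
            errs.append(f"{self.name}: unknown basis {self.basis!r}")
        if self.family not in FAMILIES:
            errs.append(f"{self.name}: unknown family {self.family!r}")
        if self.units not in UNITS:
            errs.append(f"{self.name}: unknown units {self.units!r}")
        if not (self.low <= self.base <= self.high):
            errs.append(
                f"{self.name}: range must satisfy low <= base <= high "
                f"(got {self.low}, {self.base}, {self.high})"
            )
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            errs.append(f"{self.name}: beta support must lie in [0, 1]")
        if self.family == "gamma" and self.low <= 0.0:
            errs.append(f"{self.name}: gamma requires low > 0")
        if errs:
            raise ParameterValidationError("; ".join(errs))

    def fitted(self) -> "FittedDistribution":
        """Fit the declared distribution family to (base, low, high)."""
        if self.family == "fixed" or self.low == self.high:
            return FittedDistribution("point_mass", self.base, 0.0)
        if self.family == "beta":
            return fit_beta(self.base, self.low, self.high, name=self.name)
        return fit_gamma(self.base, self.low, self.high, name=self.name)


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted beta, gamma, or degenerate (point-mass) distribution.

    ``shape_a`` is alpha (beta) or the shape k (gamma); ``shape_b_or_scale``
    is beta's beta or gamma's scale theta.  For a point mass ``shape_a``
    holds the support point.
    """

    family: str  # beta | gamma | point_mass
    shape_a: float
    shape_b_or_scale: float

    def mean(self) -> float:
        if self.family == "point_mass":
            return self.shape_a
        if self.family == "beta":
            return self.shape_a / (self.shape_a + self.shape_b_or_scale)
        return self.shape_a * self.shape_b_or_scale

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "point_mass":
            return self.shape_a if size is None else np.full(size, self.shape_a)
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b_or_scale, size=size)
        return rng.gamma(self.shape_a, self.shape_b_or_scale, size=size)


def fit_beta(mean: float, low: float, high: float, name: str = "") -> FittedDistribution:
    """Method-of-moments beta from a mean and a central 95% range.

    The stated [low, high] range is read as a central 95% interval, so the
    standard deviation is (high - low) / 3.92; alpha and beta then follow
    from the mean and variance.  A zero-width range degenerates to a point
    mass.
    """
    if not (0.0 < mean < 1.0):
        if low == mean == high:  # boundary point mass (e.g. probability 0 or 1)
            return FittedDistribution("point_mass", mean, 0.0)
        raise ParameterValidationError(f"{name or 'beta'}: mean must be in (0, 1), got {mean}")
    if not (low <= mean <= high):
        raise ParameterValidationError(f"{name or 'beta'}: need low <= mean <= high")
    if high == low:
        return FittedDistribution("point_mass", mean, 0.0)
    sigma = (high - low) / Z95_WIDTH
    nu = mean * (1.0 - mean) / sigma**2 - 1.0
    alpha, beta = mean * nu, (1.0 - mean) * nu
    if alpha <= 0.0 or beta <= 0.0:
        raise ParameterValidationError(
            f"{name or 'beta'}: range ({low}, {high}) too wide for mean {mean} "
            f"(implied alpha={alpha:.4g}, beta={beta:.4g})"
        )
    return FittedDistribution("beta", alpha, beta)


def fit_gamma(mean: float, low: float, high: float, name: str = "") -> FittedDistribution:
    """Method-of-moments gamma (shape, scale) from a mean and 95% range."""
    if low <= 0.0:
        raise ParameterValidationError(f"{name or 'gamma'}: gamma requires low > 0, got {low}")
    if not (low <= mean <= high):
        raise ParameterValidationError(f"{name or 'gamma'}: need low <= mean <= high")
    if high == low:
        return FittedDistribution("point_mass", mean, 0.0)
    sigma = (high - low) / Z95_WIDTH
    return FittedDistribution("gamma", mean**2 / sigma**2, sigma**2 / mean)


def hr_to_probability(p_reference: float, hazard_ratio: float) -> float:
    """Scale an annual event probability by a hazard ratio, capped at 1.

    The ratio is applied multiplicatively on the probability scale
    (0.232 x 1.81 = 0.419), matching how the poor-adherence hospitalization
    probability was derived from the good-adherence one.
    """
    if not (0.0 <= p_reference <= 1.0):
        raise ValueError(f"p_reference must be a probability, got {p_reference}")
    if hazard_ratio <= 0.0:
        raise ValueError(f"hazard_ratio must be positive, got {hazard_ratio}")
    return min(p_reference * hazard_ratio, 1.0)


def intervention_adherence(p_usual: float, gain: float) -> float:
    """Good-adherence probability under the intervention: base + gain, capped at 1."""
    if not (0.0 <= p_usual <= 1.0 and 0.0 <= gain <= 1.0):
        raise ValueError("p_usual and gain must lie in [0, 1]")
    return min(p_usual + gain, 1.0)


def inflate_cost(amount: float, cpi_from: float, cpi_to: float) -> float:
    """CPI-adjust a dollar amount between index years."""
    if cpi_from <= 0.0 or cpi_to <= 0.0:
        raise ParameterValidationError("CPI indices must be positive")
    return amount * cpi_to / cpi_from


class ParameterSet:
    """The complete, validated input set: 18 table rows plus model constants.

    Behaves as a read-only mapping from parameter name to base value
    (constants included), with :meth:`spec` and :meth:`fitted` exposing the
    full uncertainty description.
    """

    def __init__(self, specs: Mapping[str, ParameterSpec], constants: Mapping[str, float]):
        self.specs = dict(specs)
        self.constants = {k: float(v) for k, v in constants.items()}
        self._validate()

    def _validate(self) -> None:
        missing = [n for n in TABLE_NAMES if n not in self.specs]
        if missing:
            raise ParameterValidationError(f"missing parameters: {', '.join(missing)}")
        unknown = [n for n in self.specs if n not in TABLE_NAMES]
        if unknown:
            raise ParameterValidationError(f"unknown parameters: {', '.join(unknown)}")
        missing_c = [n for n in CONSTANT_NAMES if n not in self.constants]
        if missing_c:
            raise ParameterValidationError(f"missing constants: {', '.join(missing_c)}")
        for spec in self.specs.values():
            spec.validate()

    # -- mapping interface over base values -------------------------------
    def __getitem__(self, name: str) -> float:
        if name in self.specs:
            return self.specs[name].base
        return self.constants[name]

    def __contains__(self, name: str) -> bool:
        return name in self.specs or name in self.constants

    def __iter__(self) -> Iterator[str]:
        yield from self.specs
        yield from self.constants

    def spec(self, name: str) -> ParameterSpec:
        return self.specs[name]

    def base_values(self) -> dict[str, float]:
        """Base value of every table parameter (constants excluded)."""
        return {n: s.base for n, s in self.specs.items()}

    def fitted(self) -> dict[str, FittedDistribution]:
        """Fitted sampling distribution for every table parameter."""
        return {n: s.fitted() for n, s in self.specs.items()}

    def with_overrides(self, **base_overrides: float) -> "ParameterSet":
        """Copy with some base values replaced (ranges shifted to contain them)."""
        specs = dict(self.specs)
        for name, value in base_overrides.items():
            if name not in specs:
                raise ParameterValidationError(f"unknown parameter: {name}")
            s = specs[name]
            specs[name] = replace(
                s, base=value, low=min(s.low, value), high=max(s.high, value)
            )
        return ParameterSet(specs, self.constants)

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "name": s.name,
                    "base": s.base,
                    "low": s.low,
                    "high": s.high,
                    "basis": s.basis,
                    "family": s.family,
                    "units": s.units,
                }
                for s in (self.specs[n] for n in TABLE_NAMES)
            ],
            "constants": dict(self.constants),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ParameterSet":
        try:
            rows = payload["parameters"]
            constants = payload["constants"]
        except (KeyError, TypeError) as exc:
            raise ParameterValidationError(f"config missing top-level key: {exc}") from None
        specs: dict[str, ParameterSpec] = {}
        required = {"name", "base", "low", "high", "basis", "family", "units"}
        for row in rows:
            missing = required - set(row)
            if missing:
                raise ParameterValidationError(
                    f"parameter record {row.get('name', '<unnamed>')!r} "
                    f"missing keys: {', '.join(sorted(missing))}"
                )
            name = row["name"]
            if name in specs:
                raise ParameterValidationError(f"duplicate parameter: {name}")
            specs[name] = ParameterSpec(
                name=name,
                base=float(row["base"]),
                low=float(row["low"]),
                high=float(row["high"]),
                basis=row["basis"],
                family=row["family"],
                units=row["units"],
            )
        return cls(specs, constants)


def _bundled_config_text() -> str:
    return resources.files("hfcea.data").joinpath("parameters.yaml").read_text()


def load_parameter_set(config_path=None) -> ParameterSet:
    """Load and validate a parameter configuration (bundled defaults if None)."""
    if config_path is None:
        text = _bundled_config_text()
    else:
        text = Path(config_path).read_text()
    payload = yaml.safe_load(text)
    return ParameterSet.from_dict(payload)


def sampling_check(dist: FittedDistribution, n: int = 1_000_000, seed: int = 0) -> tuple[float, float]:
    """Sample mean and its standard error, for cross-checking fitted moments."""
    rng = np.random.default_rng(seed)
    draws = dist.sample(rng, size=n)
    return float(np.mean(draws)), float(np.std(draws, ddof=1) / math.sqrt(n))
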