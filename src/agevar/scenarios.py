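"""Generative models of individual ageing trajectories and their population moments.

Four linear decline scenarios for a physiological function (muscle power,
VO2max, cognition, ...) between a baseline age ``t0`` (default 30 y) and a
maximum age ``t_max`` (default 80 y):

S1 (uniform relative)
    every individual loses the same *fraction* ``r`` of their own baseline
    per year: ``v(t) = b * (1 - r * (t - t0))``.  Note the loss is linear in
    the baseline value, not compounding: at ``r = 0.01`` an individual
    retains exactly 50 % of baseline at age 80.
S2 (uniform absolute)
    every individual loses the same *absolute* amount ``d`` per year:
    ``v(t) = b - d * (t - t0)``.
S3 (random individual slopes)
    each individual has their own constant loss rate ``d_i`` drawn from a
    truncated normal, independent of baseline: ``v(t) = b - d_i * (t - t0)``.
S4 (convergent decline)
    the better the start, the faster the loss; individual losses are
    proportional to the distance above a common floor ``c``:
    ``v(t) = c + (b - c) * (1 - k * (t - t0))``.  With ``c = 0`` this is
    identical to S1 with ``r = k``.

Because the linear forms are only physiologically meaningful while the
function value stays non-negative, the population model restricts baselines
(and, for S3, slopes) to the region where every trajectory remains >= 0 over
``[t0, t_max]``; see :func:`baseline_lower_bound`.  All closed-form moments
use the moments of these *truncated* distributions, so they describe the
population actually being generated.
"""

from __future__ import annotations

import enum
import json
import math
from collections import namedtuple
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import stats

from .errors import SpecError, TrajectoryError

__all__ = [
    "Scenario",
    "ScenarioSpec",
    "IndividualDraw",
    "MomentPoint",
    "value_at",
    "analytic_moments",
    "moment_trajectory",
    "baseline_lower_bound",
    "baseline_moments",
    "slope_moments",
]


class Scenario(str, enum.Enum):
    """Identifier of one of the four generative decline models."""

    S1_UNIFORM_RELATIVE = "S1_uniform_relative"
    S2_UNIFORM_ABSOLUTE = "S2_uniform_absolute"
    S3_RANDOM_INDIVIDUAL = "S3_random_individual"
    S4_CONVERGENT = "S4_convergent"

    @classmethod
    def parse(cls, value: "Scenario | str") -> "Scenario":
        """Accept a Scenario, a full value ('S1_uniform_relative') or a
        short id ('S1' ... 'S4'), case-insensitively."""
        if isinstance(value, Scenario):
            return value
        text = str(value).strip()
        for member in cls:
            if text.lower() in (member.value.lower(), member.short.lower()):
                return member
        raise SpecError(f"unknown scenario identifier: {value!r}")

    @property
    def short(self) -> str:
        return self.value.split("_", 1)[0]


#: (age, mean, sd, covar_percent) of the noise-free population at one age.
MomentPoint = namedtuple("MomentPoint", ["age", "mean", "sd", "covar"])


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterisation of one generative decline model.

    Parameters
    ----------
    scenario_id:
        Which of the four decline models to use.
    baseline_age, max_age:
        Age range [t0, t_max] (years) over which the model is defined.
    baseline_mean, baseline_sd:
        Mean and SD (function units) of the normal distribution baselines
        are drawn from, before truncation to the model's validity region.
    relative_rate:
        S1 only — fraction of baseline lost per year (default 0.01/yr, i.e.
        50 % of baseline retained at age 80 from age 30).
    absolute_rate:
        S2 only — function units lost per year.
    slope_mean, slope_sd, slope_cap:
        S3 only — individual loss rates are drawn from
        Normal(slope_mean, slope_sd) truncated to [0, slope_cap].
        ``slope_cap=None`` means ``slope_mean + 3 * slope_sd``.  The cap
        bounds the worst-case total loss so baselines can be restricted to
        keep every trajectory non-negative.
    convergence_floor, convergence_rate:
        S4 only — common floor c (function units) and per-year convergence
        rate k towards it.
    noise_sd:
        SD of additive measurement noise (function units), applied to
        observations in all scenarios.
    """

    scenario_id: Scenario
    baseline_age: float = 30.0
    max_age: float = 80.0
    baseline_mean: float = 80.0
    baseline_sd: float = 20.0
    relative_rate: float = 0.01
    absolute_rate: float = 1.0
    slope_mean: float = 0.5
    slope_sd: float = 0.3
    slope_cap: float | None = None
    convergence_floor: float = 20.0
    convergence_rate: float = 0.016
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario_id", Scenario.parse(self.scenario_id))
        if not self.max_age > self.baseline_age:
            raise SpecError("max_age must exceed baseline_age")
        if not self.baseline_mean > 0:
            raise SpecError("baseline_mean must be > 0")
        for name in ("baseline_sd", "relative_rate", "absolute_rate", "slope_mean",
                     "slope_sd", "convergence_floor", "convergence_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        span = self.span
        sid = self.scenario_id
        if sid is Scenario.S1_UNIFORM_RELATIVE and self.relative_rate * span > 1 + 1e-12:
            raise SpecError(
                f"relative_rate * (max_age - baseline_age) = "
                f"{self.relative_rate * span:g} exceeds 1: function value would "
                "go negative within the age range")
        if sid is Scenario.S4_CONVERGENT and self.convergence_rate * span > 1 + 1e-12:
            raise SpecError(
                f"convergence_rate * (max_age - baseline_age) = "
                f"{self.convergence_rate * span:g} exceeds 1: trajectories would "
                "cross the convergence floor")
        if sid is Scenario.S3_RANDOM_INDIVIDUAL:
            cap = self.effective_slope_cap
            if cap < 0:
                raise SpecError("slope_cap must be >= 0")
            if self.slope_sd == 0 and not (0 <= self.slope_mean <= cap):
                raise SpecError("with slope_sd = 0, slope_mean must lie in [0, slope_cap]")

    @property
    def span(self) -> float:
        """Width of the modelled age range, t_max - t0 (years)."""
        return self.max_age - self.baseline_age

    @property
    def effective_slope_cap(self) -> float:
        cap = self.slope_cap
        return self.slope_mean + 3.0 * self.slope_sd if cap is None else cap

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["scenario_id"] = self.scenario_id.value
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "ScenarioSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise SpecError(f"unknown ScenarioSpec keys: {sorted(unknown)}")
        if "scenario_id" not in mapping:
            raise SpecError("missing required key 'scenario_id'")
        return cls(**mapping)

    def to_file(self, path: str | Path) -> None:
        """Write the spec as a flat YAML (or JSON, by extension) mapping."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text())  # YAML is a JSON superset
        if not isinstance(raw, dict):
            raise SpecError(f"config file {path} does not contain a mapping")
        return cls.from_dict(raw)


@dataclass(frozen=True)
class IndividualDraw:
    """One simulated individual: baseline value at t0 and, for S3, their
    personal loss rate (units/year).  ``slope`` is zero and ignored for the
    other scenarios."""

    subject_id: str
    baseline: float
    slope: float = 0.0

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise SpecError(f"baseline of {self.subject_id} must be > 0")
        if self.slope < 0:
            raise SpecError(f"slope of {self.subject_id} must be >= 0")


# --------------------------------------------------------------------------
# truncation bounds and truncated moments
# --------------------------------------------------------------------------

def baseline_lower_bound(spec: ScenarioSpec) -> float:
    """Lowest admissible baseline for the scenario's validity region.

    The bound guarantees every generated trajectory stays >= 0 across
    [t0, t_max]: S1 needs only b > 0 (r*span <= 1 is enforced), S2 needs
    b >= d*span, S3 needs b >= slope_cap*span, and S4 needs b >= c.
    """
    sid = spec.scenario_id
    if sid is Scenario.S2_UNIFORM_ABSOLUTE:
        return max(0.0, spec.absolute_rate * spec.span)
    if sid is Scenario.S3_RANDOM_INDIVIDUAL:
        return max(0.0, spec.effective_slope_cap * spec.span)
    if sid is Scenario.S4_CONVERGENT:
        return max(0.0, spec.convergence_floor)
    return 0.0


def baseline_moments(spec: ScenarioSpec) -> tuple[float, float]:
    """(mean, sd) of the truncated-normal baseline distribution."""
    lb = baseline_lower_bound(spec)
    mu, sigma = spec.baseline_mean, spec.baseline_sd
    if sigma == 0.0:
        if mu <= lb and lb > 0:
            raise SpecError(
                f"baseline_sd = 0 with baseline_mean {mu:g} at or below the "
                f"scenario's baseline floor {lb:g}")
        return mu, 0.0
    a = (lb - mu) / sigma
    mean, var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
    return float(mean), float(math.sqrt(var))


def slope_moments(spec: ScenarioSpec) -> tuple[float, float]:
    """(mean, sd) of the truncated-normal S3 slope distribution on
    [0, slope_cap]."""
    if spec.scenario_id is not Scenario.S3_RANDOM_INDIVIDUAL:
        return 0.0, 0.0
    mu, sigma = spec.slope_mean, spec.slope_sd
    cap = spec.effective_slope_cap
    if sigma == 0.0:
        return mu, 0.0
    a, b = (0.0 - mu) / sigma, (cap - mu) / sigma
    mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(mean), float(math.sqrt(var))


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def _check_age(spec: ScenarioSpec, age: float) -> float:
    if not (spec.baseline_age <= age <= spec.max_age):
        raise TrajectoryError(
            f"age {age:g} outside the modelled range "
            f"[{spec.baseline_age:g}, {spec.max_age:g}]")
    return age - spec.baseline_age


def trajectory_values(
    spec: ScenarioSpec,
    baselines: np.ndarray,
    slopes: np.ndarray,
    ages: np.ndarray,
    subject_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Vectorised noise-free trajectory evaluation.

    ``ages`` broadcasts against ``baselines``/``slopes``.  Raises
    :class:`TrajectoryError` if any age is out of range or any value is
    negative (the linear models are not valid there; values are never
    silently clipped).
    """
    baselines = np.asarray(baselines, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < spec.baseline_age) or np.any(ages > spec.max_age):
        bad = float(ages[(ages < spec.baseline_age) | (ages > spec.max_age)].flat[0])
        raise TrajectoryError(
            f"age {bad:g} outside the modelled range "
            f"[{spec.baseline_age:g}, {spec.max_age:g}]")
    tau = ages - spec.baseline_age
    sid = spec.scenario_id
    if sid is Scenario.S1_UNIFORM_RELATIVE:
        values = baselines * (1.0 - spec.relative_rate * tau)
    elif sid is Scenario.S2_UNIFORM_ABSOLUTE:
        values = baselines - spec.absolute_rate * tau
    elif sid is Scenario.S3_RANDOM_INDIVIDUAL:
        values = baselines - slopes * tau
    else:
        c = spec.convergence_floor
        values = c + (baselines - c) * (1.0 - spec.convergence_rate * tau)
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        idx = int(np.argmin(values))
        flat_ages = np.broadcast_to(ages, values.shape)
        who = subject_ids[idx] if subject_ids is not None else f"index {idx}"
        raise TrajectoryError(
            f"trajectory of subject {who} is negative "
            f"({values.flat[idx]:g}) at age {flat_ages.flat[idx]:g}; choose "
            "parameters for which the linear decline model stays non-negative")
    return values


def value_at(spec: ScenarioSpec, draw: IndividualDraw, age: float) -> float:
    """Noise-free function value of one individual at ``age``.

    Raises :class:`TrajectoryError` for an age outside [t0, t_max] or a
    negative computed value (possible in S2/S3 with extreme parameters).
    """
    _check_age(spec, age)
    out = trajectory_values(
        spec,
        np.array([draw.baseline]),
        np.array([draw.slope]),
        np.array([age]),
        subject_ids=[draw.subject_id],
    )
    return float(out[0])


# --------------------------------------------------------------------------
# closed-form population moments
# --------------------------------------------------------------------------

def analytic_moments(spec: ScenarioSpec, age: float) -> MomentPoint:
    """Noise-free population (mean, sd, covar%) at ``age``.

    COVAR follows the conventional definition 100 * (SD / mean).  The
    moments are those of the truncated baseline (and, for S3, slope)
    distributions the simulator actually draws from, so that large
    simulated cohorts converge on these curves exactly.
    """
    tau = _check_age(spec, age)
    mu0, s0 = baseline_moments(spec)
    sid = spec.scenario_id
    if sid is Scenario.S1_UNIFORM_RELATIVE:
        shrink = 1.0 - spec.relative_rate * tau
        mean, sd = mu0 * shrink, s0 * shrink
    elif sid is Scenario.S2_UNIFORM_ABSOLUTE:
        mean, sd = mu0 - spec.absolute_rate * tau, s0
    elif sid is Scenario.S3_RANDOM_INDIVIDUAL:
        md, sdl = slope_moments(spec)
        mean = mu0 - md * tau
        sd = math.sqrt(s0 ** 2 + tau ** 2 * sdl ** 2)
    else:
        c = spec.convergence_floor
        shrink = 1.0 - spec.convergence_rate * tau
        mean, sd = c + (mu0 - c) * shrink, s0 * shrink
    if mean <= 0:
        raise TrajectoryError(
            f"population mean non-positive at age {age:g}; COVAR undefined")
    return MomentPoint(age=float(age), mean=mean, sd=sd, covar=100.0 * sd / mean)


def moment_trajectory(spec: ScenarioSpec, ages: Iterable[float]) -> list[MomentPoint]:
    """:func:`analytic_moments` over a strictly increasing list of ages."""
    ages = [float(a) for a in ages]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise TrajectoryError("ages must be strictly increasing")
    out = []
    for age in ages:
        try:
            out.append(analytic_moments(spec, age))
        except TrajectoryError as exc:
            raise TrajectoryError(f"at age {age:g}: {exc}") from exc
    return out
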