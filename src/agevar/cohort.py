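"""Cohort simulation and cohort file I/O.

A :class:`CohortSample` is a tidy table of (subject_id, age, value)
observations, either cross-sectional (one observation per subject — the
design the dispersion framework is meant for) or longitudinal (every
subject observed at several ages — the ground-truth design the framework
substitutes for).

Randomness: one integer seed drives the whole simulation.  Internally the
seed is split into independent sub-streams for baselines, slopes,
observation ages and measurement noise, so e.g. switching noise on does not
perturb which individuals are drawn.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CohortError, SpecError
from .scenarios import (
    IndividualDraw,
    Scenario,
    ScenarioSpec,
    baseline_lower_bound,
    trajectory_values,
)

__all__ = [
    "Design",
    "CohortSample",
    "draw_individuals",
    "simulate_cross_sectional",
    "simulate_longitudinal",
    "exemplar_cohort",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ("subject_id", "age", "value")

#: exemplar baselines for the three-individual illustrative cohorts
_EXEMPLAR_BASELINES = (100.0, 80.0, 60.0)
#: fixed S3 exemplar slopes (rapid / barely any / modest decline for the
#: best / intermediate / worst starter).  The assignment is deliberately
#: unordered with respect to baseline — ordered assignments degenerate into
#: the convergent scenario — and keeps every trajectory positive to age 80.
_EXEMPLAR_S3_SLOPES = (1.6, 0.1, 0.8)


class Design(str, enum.Enum):
    CROSS_SECTIONAL = "cross_sectional"
    LONGITUDINAL = "longitudinal"


@dataclass
class CohortSample:
    """Tidy collection of observations of one physiological function.

    ``data`` has exactly the columns ``subject_id`` (str), ``age`` (years)
    and ``value`` (function units).
    """

    data: pd.DataFrame
    design: Design
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != list(COHORT_COLUMNS):
            raise CohortError(
                f"cohort table must have columns {COHORT_COLUMNS}, got "
                f"{list(df.columns)}")
        if len(df) == 0:
            raise CohortError("empty cohort")
        ages = df["age"].to_numpy(dtype=float)
        values = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or np.any(ages < 0):
            raise CohortError("all ages must be finite and >= 0")
        if not np.all(np.isfinite(values)):
            raise CohortError("all values must be finite")
        counts = df["subject_id"].value_counts()
        self.design = Design(self.design)
        if self.design is Design.CROSS_SECTIONAL:
            if counts.max() > 1:
                raise CohortError(
                    "cross-sectional design requires one observation per subject")
        else:
            n_ages = df.groupby("subject_id")["age"].nunique()
            if (n_ages < 2).any():
                raise CohortError(
                    "longitudinal design requires >= 2 distinct ages per subject")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("baseline", "slope", "age", "noise")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _rejection_sample(
    rng: np.random.Generator,
    n: int,
    mu: float,
    sigma: float,
    lo: float,
    hi: float = np.inf,
    what: str = "baseline",
) -> np.ndarray:
    """Draw n values from Normal(mu, sigma) restricted to [lo, hi] by
    rejection.  Raises SpecError if the acceptance rate drops below 1 %."""
    out = np.empty(0)
    proposed = accepted = 0
    while out.size < n:
        batch = max(n - out.size, 1000)
        cand = rng.normal(mu, sigma, size=batch)
        keep = cand[(cand >= lo) & (cand <= hi)]
        proposed += batch
        accepted += keep.size
        if proposed >= 10_000 and accepted < 0.01 * proposed:
            raise SpecError(
                f"degenerate truncation while drawing {what}s: acceptance rate "
                f"{accepted / proposed:.2%} (< 1%) for Normal({mu:g}, {sigma:g}) "
                f"on [{lo:g}, {hi:g}]")
        out = np.concatenate([out, keep])
    return out[:n]


def _subject_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"s{i:0{width}d}" for i in range(1, n + 1)]


def draw_individuals(spec: ScenarioSpec, n: int, seed: int) -> list[IndividualDraw]:
    """Draw ``n`` individuals (baselines and, for S3, personal slopes).

    Baselines come from Normal(baseline_mean, baseline_sd) truncated below
    at the scenario's validity floor (see
    :func:`agevar.scenarios.baseline_lower_bound`); S3 slopes from
    Normal(slope_mean, slope_sd) truncated to [0, slope_cap].  Deterministic
    given (spec, n, seed).
    """
    if n < 1:
        raise SpecError("n must be >= 1")
    rngs = _stage_rngs(seed)
    lb = baseline_lower_bound(spec)
    mu, sigma = spec.baseline_mean, spec.baseline_sd
    if sigma == 0.0:
        if mu <= lb and lb > 0:
            raise SpecError(
                f"baseline_sd = 0 with baseline_mean {mu:g} at or below the "
                f"scenario's baseline floor {lb:g}")
        baselines = np.full(n, mu)
    else:
        baselines = _rejection_sample(rngs["baseline"], n, mu, sigma, lo=lb)
        # strict positivity even when the floor is 0
        baselines = np.where(baselines == 0.0, np.nextafter(0.0, 1.0), baselines)
    if spec.scenario_id is Scenario.S3_RANDOM_INDIVIDUAL:
        if spec.slope_sd == 0.0:
            slopes = np.full(n, spec.slope_mean)
        else:
            slopes = _rejection_sample(
                rngs["slope"], n, spec.slope_mean, spec.slope_sd,
                lo=0.0, hi=spec.effective_slope_cap, what="slope")
    else:
        slopes = np.zeros(n)
    ids = _subject_ids(n)
    return [IndividualDraw(i, float(b), float(s))
            for i, b, s in zip(ids, baselines, slopes)]


def _draw_arrays(draws: Sequence[IndividualDraw]) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = [d.subject_id for d in draws]
    baselines = np.array([d.baseline for d in draws])
    slopes = np.array([d.slope for d in draws])
    return ids, baselines, slopes


def simulate_cross_sectional(spec: ScenarioSpec, n: int, seed: int) -> CohortSample:
    """Simulate a cross-sectional cohort: each subject observed once at an
    age drawn uniformly on [t0, t_max], with additive Normal(0, noise_sd)
    measurement error."""
    draws = draw_individuals(spec, n, seed)
    rngs = _stage_rngs(seed)
    ids, baselines, slopes = _draw_arrays(draws)
    ages = rngs["age"].uniform(spec.baseline_age, spec.max_age, size=n)
    values = trajectory_values(spec, baselines, slopes, ages, subject_ids=ids)
    if spec.noise_sd > 0:
        values = values + rngs["noise"].normal(0.0, spec.noise_sd, size=n)
    df = pd.DataFrame({"subject_id": ids, "age": ages, "value": values})
    return CohortSample(
        df, Design.CROSS_SECTIONAL,
        provenance=f"simulated {spec.scenario_id.short} cross-sectional n={n} seed={seed}")


def simulate_longitudinal(
    spec: ScenarioSpec, n: int, ages: Sequence[float], seed: int
) -> CohortSample:
    """Simulate a longitudinal cohort: every subject observed at every age
    in ``ages`` (>= 2 strictly increasing entries within [t0, t_max]), with
    fresh independent noise per observation."""
    ages = [float(a) for a in ages]
    if len(ages) < 2 or any(b <= a for a, b in zip(ages, ages[1:])):
        raise SpecError("ages must contain >= 2 strictly increasing entries")
    draws = draw_individuals(spec, n, seed)
    rngs = _stage_rngs(seed)
    ids, baselines, slopes = _draw_arrays(draws)
    age_arr = np.asarray(ages)
    values = trajectory_values(
        spec, baselines[:, None], slopes[:, None], age_arr[None, :], subject_ids=ids)
    if spec.noise_sd > 0:
        values = values + rngs["noise"].normal(0.0, spec.noise_sd, size=values.shape)
    df = pd.DataFrame({
        "subject_id": np.repeat(ids, len(ages)),
        "age": np.tile(age_arr, n),
        "value": values.ravel(),
    })
    return CohortSample(
        df, Design.LONGITUDINAL,
        provenance=f"simulated {spec.scenario_id.short} longitudinal n={n} seed={seed}")


def exemplar_cohort(scenario_id: Scenario | str) -> CohortSample:
    """Three-individual illustrative cohort for one scenario.

    Three subjects with baselines 100, 80 and 60 at age 30 (best,
    intermediate, worst) followed noise-free every year to age 80, using
    the default rates (S1 r=0.01; S2 d=1; S3 fixed slopes 1.6/0.1/0.8 —
    rapid, barely-any and modest decline; S4 c=20, k=0.016).
    """
    sid = Scenario.parse(scenario_id)
    spec = ScenarioSpec(scenario_id=sid, noise_sd=0.0)
    ages = np.arange(spec.baseline_age, spec.max_age + 1.0)
    slopes = (_EXEMPLAR_S3_SLOPES if sid is Scenario.S3_RANDOM_INDIVIDUAL
              else (0.0, 0.0, 0.0))
    ids = [f"s{i}" for i in (1, 2, 3)]
    values = trajectory_values(
        spec,
        np.array(_EXEMPLAR_BASELINES)[:, None],
        np.array(slopes)[:, None],
        ages[None, :],
        subject_ids=ids,
    )
    df = pd.DataFrame({
        "subject_id": np.repeat(ids, ages.size),
        "age": np.tile(ages, 3),
        "value": values.ravel(),
    })
    return CohortSample(df, Design.LONGITUDINAL,
                        provenance=f"three-individual exemplar {sid.short}")


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def write_cohort(sample: CohortSample, path: str | Path) -> None:
    """Write a cohort CSV (UTF-8, LF, header ``subject_id,age,value``).

    Floats are written with 17 significant digits so that write -> read
    round-trips records exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for sid, age, value in sample.data.itertuples(index=False):
            fh.write(f"{sid},{age:.17g},{value:.17g}\n")


def read_cohort(path: str | Path, provenance: str | None = None) -> CohortSample:
    """Read a cohort CSV written by :func:`write_cohort` (or by hand).

    The design is inferred from subject multiplicity: every subject once ->
    cross-sectional; every subject at >= 2 ages -> longitudinal.  Parse
    errors name the offending line.
    """
    path = Path(path)
    rows: list[tuple[str, float, float]] = []
    seen: set[tuple[str, float]] = set()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortError(f"{path}: empty file") from None
        if [h.strip() for h in header] != list(COHORT_COLUMNS):
            raise CohortError(
                f"{path}: line 1: header must be "
                f"'{','.join(COHORT_COLUMNS)}', got {','.join(header)!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise CohortError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(row)}")
            sid = row[0].strip()
            try:
                age = float(row[1])
                value = float(row[2])
            except ValueError:
                raise CohortError(
                    f"{path}: line {lineno}: non-numeric age or value") from None
            if not np.isfinite(age) or age < 0:
                raise CohortError(
                    f"{path}: line {lineno}: age must be finite and >= 0")
            if not np.isfinite(value):
                raise CohortError(f"{path}: line {lineno}: value must be finite")
            key = (sid, age)
            if key in seen:
                raise CohortError(
                    f"{path}: line {lineno}: duplicate (subject_id, age) pair {key}")
            seen.add(key)
            rows.append((sid, age, value))
    if not rows:
        raise CohortError(f"{path}: empty cohort (header only)")
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    counts = df["subject_id"].value_counts()
    if counts.max() == 1:
        design = Design.CROSS_SECTIONAL
    elif counts.min() >= 2:
        design = Design.LONGITUDINAL
    else:
        raise CohortError(
            f"{path}: mixed subject multiplicity (some subjects observed once, "
            "others repeatedly); neither cross-sectional nor longitudinal")
    return CohortSample(df, design, provenance=provenance or str(path))
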