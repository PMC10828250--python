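"""Scenario classification from the (SD, COVAR) direction pair.

The framework's decision rule: how the standard deviation and the
coefficient of variation of a physiological function move with age in
cross-sectional data identifies the decline scenario —

===========  ============  ==============================  ================
SD           COVAR         fine label                      coarse verdict
===========  ============  ==============================  ================
decrease     none          S1 uniform relative             uniform
none         increase      S2 uniform absolute             individualistic
increase     increase      S3 random individual slopes     individualistic
decrease     decrease      S4 convergent                   individualistic
===========  ============  ==============================  ================

A changing COVAR (up or down) always means the *relative* spread of the
population is changing, i.e. an individualistic rate of ageing; a flat
COVAR with non-increasing SD means a uniform rate.  Direction pairs not
produced by any scenario map to an indeterminate fine label; rising SD
with flat COVAR is indeterminate even at the coarse level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortSample
from .dispersion import DispersionCurve, bin_cohort, bin_edges_default
from .errors import TrendError
from .scenarios import Scenario
from .trend import Direction, Statistic, TrendResult, bootstrap_trend, wls_trend

__all__ = [
    "FineLabel",
    "CoarseLabel",
    "FrameworkVerdict",
    "classify",
    "analyze_cohort",
    "labels_for",
]

import enum


class FineLabel(str, enum.Enum):
    S1_UNIFORM_RELATIVE = Scenario.S1_UNIFORM_RELATIVE.value
    S2_UNIFORM_ABSOLUTE = Scenario.S2_UNIFORM_ABSOLUTE.value
    S3_RANDOM_INDIVIDUAL = Scenario.S3_RANDOM_INDIVIDUAL.value
    S4_CONVERGENT = Scenario.S4_CONVERGENT.value
    INDETERMINATE = "indeterminate"


class CoarseLabel(str, enum.Enum):
    UNIFORM = "uniform"
    INDIVIDUALISTIC = "individualistic"
    INDETERMINATE = "indeterminate"


_D, _N, _I = Direction.DECREASE, Direction.NONE, Direction.INCREASE

#: (sd_direction, covar_direction) -> (fine, coarse, rationale)
_MAPPING: dict[tuple[Direction, Direction], tuple[FineLabel, CoarseLabel, str]] = {
    (_D, _N): (
        FineLabel.S1_UNIFORM_RELATIVE, CoarseLabel.UNIFORM,
        "SD decreases with age while COVAR is constant: everyone loses the "
        "same fraction of their baseline per year (uniform rate of ageing)."),
    (_N, _I): (
        FineLabel.S2_UNIFORM_ABSOLUTE, CoarseLabel.INDIVIDUALISTIC,
        "SD stays constant while COVAR increases with age: everyone loses the "
        "same absolute amount per year, so in relative terms those who "
        "started lowest decline fastest (individualistic rate of ageing)."),
    (_I, _I): (
        FineLabel.S3_RANDOM_INDIVIDUAL, CoarseLabel.INDIVIDUALISTIC,
        "Both SD and COVAR increase with age: individuals decline at their "
        "own random rates (individualistic rate of ageing)."),
    (_D, _D): (
        FineLabel.S4_CONVERGENT, CoarseLabel.INDIVIDUALISTIC,
        "Both SD and COVAR decrease with age: those who started highest lose "
        "the most, trajectories converge (individualistic rate of ageing)."),
    (_N, _N): (
        FineLabel.INDETERMINATE, CoarseLabel.UNIFORM,
        "No detectable age trend in either SD or COVAR. A flat COVAR is "
        "consistent with a uniform rate of ageing, but this pattern can also "
        "simply reflect little decline over the sampled ages or an "
        "underpowered study."),
    (_I, _N): (
        FineLabel.INDETERMINATE, CoarseLabel.INDETERMINATE,
        "SD increases while COVAR is flat: absolute spread grows in step with "
        "the mean. No decline scenario produces this pattern."),
    (_N, _D): (
        FineLabel.INDETERMINATE, CoarseLabel.INDIVIDUALISTIC,
        "COVAR decreases while SD is flat: relative spread shrinks, which "
        "indicates an individualistic (convergent-like) rate of ageing, but "
        "the pattern matches no single scenario."),
    (_D, _I): (
        FineLabel.INDETERMINATE, CoarseLabel.INDIVIDUALISTIC,
        "COVAR increases while SD decreases: relative spread grows, an "
        "individualistic rate of ageing, but the pattern matches no single "
        "scenario."),
    (_I, _D): (
        FineLabel.INDETERMINATE, CoarseLabel.INDIVIDUALISTIC,
        "COVAR decreases while SD increases: relative spread changes with "
        "age, an individualistic rate of ageing, but the pattern matches no "
        "single scenario."),
}


def labels_for(
    sd_direction: Direction, covar_direction: Direction
) -> tuple[FineLabel, CoarseLabel, str]:
    """(fine label, coarse label, rationale) for a direction pair."""
    return _MAPPING[(Direction(sd_direction), Direction(covar_direction))]


@dataclass(frozen=True)
class FrameworkVerdict:
    """Outcome of the framework applied to one cohort."""

    sd_direction: Direction
    covar_direction: Direction
    fine_label: FineLabel
    coarse_label: CoarseLabel
    rationale: str
    evidence: dict[str, TrendResult]
    curve: DispersionCurve | None = None

    def to_dict(self) -> dict:
        out = {
            "sd_direction": self.sd_direction.value,
            "covar_direction": self.covar_direction.value,
            "fine_label": self.fine_label.value,
            "coarse_label": self.coarse_label.value,
            "rationale": self.rationale,
            "evidence": {k: v.to_dict() for k, v in self.evidence.items()},
        }
        if self.curve is not None:
            out["dispersion"] = self.curve.to_json_dict()
        return out


def classify(
    sd_trend: TrendResult,
    covar_trend: TrendResult,
    curve: DispersionCurve | None = None,
) -> FrameworkVerdict:
    """Map a pair of SD/COVAR trend results to the framework's verdict.

    ``sd_trend`` must carry the SD statistic and ``covar_trend`` the COVAR
    statistic (each exactly once).
    """
    if sd_trend.statistic is not Statistic.SD or covar_trend.statistic is not Statistic.COVAR:
        raise TrendError(
            "classify expects (sd_trend with statistic=SD, covar_trend with "
            f"statistic=COVAR); got ({sd_trend.statistic.value}, "
            f"{covar_trend.statistic.value})")
    sd_dir, covar_dir = sd_trend.direction, covar_trend.direction
    fine, coarse, rationale = labels_for(sd_dir, covar_dir)
    return FrameworkVerdict(
        sd_direction=sd_dir, covar_direction=covar_dir,
        fine_label=fine, coarse_label=coarse, rationale=rationale,
        evidence={"sd": sd_trend, "covar": covar_trend}, curve=curve)


def analyze_cohort(
    sample: CohortSample,
    edges: Sequence[float] | None = None,
    method: str = "wls",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    min_n: int = 10,
) -> FrameworkVerdict:
    """Full pipeline: bin a cross-sectional cohort, infer the SD and COVAR
    age trends, and classify the population.

    Parameters
    ----------
    edges:
        Bin edges; ``None`` uses 10-year default bins over the observed age
        range.
    method:
        ``"wls"`` (delta-method weighted least squares) or ``"bootstrap"``
        (stratified percentile bootstrap, recommended for real data).
    seed:
        Drives the bootstrap only; two independent sub-seeds are derived
        for the SD and COVAR resamples.
    """
    if edges is None:
        ages = sample.data["age"]
        edges = bin_edges_default(float(ages.min()), float(ages.max()))
    if method in ("wls", "wls_delta"):
        curve = bin_cohort(sample, edges, min_n=min_n)
        sd_trend = wls_trend(curve, Statistic.SD, alpha=alpha)
        covar_trend = wls_trend(curve, Statistic.COVAR, alpha=alpha)
    elif method == "bootstrap":
        curve = bin_cohort(sample, edges, min_n=min_n)
        seed_sd, seed_cv = (int(s) for s in
                            np.random.SeedSequence(seed).generate_state(2) >> 1)
        sd_trend = bootstrap_trend(sample, Statistic.SD, edges,
                                   n_boot=n_boot, alpha=alpha, seed=seed_sd,
                                   min_n=min_n)
        covar_trend = bootstrap_trend(sample, Statistic.COVAR, edges,
                                      n_boot=n_boot, alpha=alpha, seed=seed_cv,
                                      min_n=min_n)
    else:
        raise TrendError(f"unknown trend method {method!r}; use 'wls' or 'bootstrap'")
    return classify(sd_trend, covar_trend, curve=curve)
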