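"""Age-resolved dispersion statistics of a cross-sectional cohort.

Groups subjects into age bins and reports, per bin, the sample size, mean,
sample SD (denominator n-1) and coefficient of variation
COVAR = 100 * SD / mean (%).  These binned curves are the quantities whose
age trends the classification framework interprets.

Bins follow the half-open convention [lo, hi), except the final bin which
is closed at its upper edge so the oldest subjects are not dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortSample, Design
from .errors import BinningError

__all__ = ["AgeBinStats", "DispersionCurve", "bin_cohort", "bin_edges_default"]


@dataclass(frozen=True)
class AgeBinStats:
    """Summary statistics of one age bin."""

    bin_lo: float
    bin_hi: float
    n: int
    mean: float
    sd: float
    covar: float  # percent, 100 * sd / mean

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.bin_lo + self.bin_hi)

    def to_dict(self) -> dict:
        return {
            "bin_lo": self.bin_lo, "bin_hi": self.bin_hi,
            "midpoint": self.midpoint, "n": self.n,
            "mean": self.mean, "sd": self.sd, "covar": self.covar,
        }


@dataclass
class DispersionCurve:
    """Ordered per-bin dispersion statistics of one cohort."""

    bins: list[AgeBinStats]
    source: str = ""

    def __post_init__(self) -> None:
        mids = [b.midpoint for b in self.bins]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise BinningError("bins must be ordered by strictly increasing midpoint")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bins])

    def statistic_values(self, statistic: str) -> np.ndarray:
        """Per-bin values of 'sd', 'covar' or 'mean' (lowercase)."""
        return np.array([getattr(b, statistic) for b in self.bins])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([b.to_dict() for b in self.bins],
                            columns=["bin_lo", "bin_hi", "midpoint", "n",
                                     "mean", "sd", "covar"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def to_json_dict(self) -> dict:
        return {"source": self.source, "bins": [b.to_dict() for b in self.bins]}


def bin_edges_default(t0: float, t_max: float, width: float = 10.0) -> np.ndarray:
    """Equal-width bin edges covering [t0, t_max].

    If the span is not a multiple of ``width`` the final bin absorbs the
    remainder, e.g. (30, 75, 10) -> 30, 40, 50, 60, 75.  At least three
    bins must result.
    """
    if width <= 0:
        raise BinningError("bin width must be > 0")
    span = t_max - t0
    if span < 3 * width:
        raise BinningError(
            f"age span {span:g} with width {width:g} yields fewer than 3 bins; "
            "at least 3 bins are required")
    n_full = int(np.floor(span / width + 1e-9))
    if abs(span - n_full * width) < 1e-9 * max(1.0, span):
        edges = t0 + width * np.arange(n_full + 1)
    else:
        edges = np.append(t0 + width * np.arange(n_full), t_max)
    return edges


def bin_cohort(
    sample: CohortSample,
    edges: Sequence[float],
    min_n: int = 10,
) -> DispersionCurve:
    """Bin a cross-sectional cohort and compute per-bin mean, SD and COVAR.

    Parameters
    ----------
    sample:
        Cross-sectional cohort (longitudinal input is rejected: repeated
        measures would violate the independence the per-bin statistics
        assume).
    edges:
        Strictly increasing bin edges (>= 4 edges, i.e. >= 3 bins) covering
        every observed age.
    min_n:
        Minimum subjects per bin (default 10; must be >= 2 for the sample
        SD to exist).
    """
    if sample.design is not Design.CROSS_SECTIONAL:
        raise BinningError(
            "dispersion binning requires a cross-sectional cohort; got "
            "longitudinal data (repeated measures per subject)")
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 4:
        raise BinningError("need >= 4 edges (>= 3 bins) for a trend fit")
    if np.any(np.diff(edges) <= 0):
        raise BinningError("bin edges must be strictly increasing")
    if min_n < 2:
        raise BinningError("min_n must be >= 2")

    ages = sample.data["age"].to_numpy(dtype=float)
    values = sample.data["value"].to_numpy(dtype=float)
    if ages.min() < edges[0] or ages.max() > edges[-1]:
        raise BinningError(
            f"ages [{ages.min():g}, {ages.max():g}] fall outside the bin edges "
            f"[{edges[0]:g}, {edges[-1]:g}]")
    # half-open [lo, hi); the final bin is closed at t_max
    idx = np.searchsorted(edges, ages, side="right") - 1
    idx[ages == edges[-1]] = edges.size - 2

    n_bins = edges.size - 1
    counts = np.bincount(idx, minlength=n_bins)
    under = [f"[{edges[i]:g}, {edges[i + 1]:g})" for i in range(n_bins)
             if counts[i] < min_n]
    if under:
        raise BinningError(
            f"underpopulated bin(s) with fewer than min_n={min_n} subjects: "
            + ", ".join(under))

    bins = []
    for i in range(n_bins):
        vals = values[idx == i]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if mean <= 0:
            raise BinningError(
                f"bin [{edges[i]:g}, {edges[i + 1]:g}) has mean {mean:g} <= 0; "
                "COVAR undefined")
        bins.append(AgeBinStats(
            bin_lo=float(edges[i]), bin_hi=float(edges[i + 1]),
            n=int(counts[i]), mean=mean, sd=sd, covar=100.0 * sd / mean))
    return DispersionCurve(bins, source=sample.provenance)
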