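"""Age-trend inference for binned dispersion statistics.

Decides whether a per-bin statistic (SD, COVAR or MEAN) increases,
decreases or shows no detectable change across age.  The decision rule is
the sign of a two-sided confidence interval for the slope of the statistic
against bin midpoint: CI wholly below zero -> decrease, wholly above ->
increase, straddling zero (including a degenerate zero-width CI at zero) ->
none.

Two methods are provided:

``wls_trend``
    weighted least squares on the per-bin statistic with weights from
    asymptotic (delta-method) standard errors.  Fast and adequate for
    simulated data; the CV standard error is a normal-theory approximation.
``bootstrap_trend``
    a stratified bootstrap that resamples subjects with replacement within
    each age bin and takes a percentile interval over the replicate slopes.
    Distribution-free; the recommended method for real data.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import CohortSample
from .dispersion import DispersionCurve, bin_cohort
from .errors import TrendError

__all__ = [
    "Statistic",
    "Direction",
    "TrendResult",
    "wls_trend",
    "bootstrap_trend",
    "direction_of",
]

logger = logging.getLogger(__name__)


class Statistic(str, enum.Enum):
    SD = "SD"
    COVAR = "COVAR"
    MEAN = "MEAN"


class Direction(str, enum.Enum):
    DECREASE = "decrease"
    NONE = "none"
    INCREASE = "increase"


def _call_direction(ci_low: float, ci_high: float) -> Direction:
    if ci_high < 0:
        return Direction.DECREASE
    if ci_low > 0:
        return Direction.INCREASE
    return Direction.NONE


@dataclass(frozen=True)
class TrendResult:
    """Slope of a dispersion statistic against age, with CI and direction."""

    statistic: Statistic
    slope: float
    ci_low: float
    ci_high: float
    alpha: float
    method: str  # "wls_delta" or "bootstrap"
    n_boot: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise TrendError(
                f"inconsistent trend result: slope {self.slope:g} outside CI "
                f"[{self.ci_low:g}, {self.ci_high:g}]")

    @property
    def direction(self) -> Direction:
        return _call_direction(self.ci_low, self.ci_high)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic.value,
            "slope": self.slope,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "method": self.method,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "direction": self.direction.value,
        }


def direction_of(result: TrendResult) -> Direction:
    """Three-way direction call from the CI-sign rule."""
    return result.direction


# --------------------------------------------------------------------------
# asymptotic standard errors (delta method / normal theory)
# --------------------------------------------------------------------------

def _bin_standard_errors(curve: DispersionCurve, statistic: Statistic) -> np.ndarray:
    n = np.array([b.n for b in curve.bins], dtype=float)
    sd = curve.statistic_values("sd")
    if statistic is Statistic.SD:
        return sd / np.sqrt(2.0 * (n - 1.0))
    if statistic is Statistic.MEAN:
        return sd / np.sqrt(n)
    cv = curve.statistic_values("covar")
    return cv * np.sqrt(1.0 / (2.0 * (n - 1.0)) + (cv / 100.0) ** 2 / n)


def _statistic_values(curve: DispersionCurve, statistic: Statistic) -> np.ndarray:
    return curve.statistic_values(statistic.value.lower())


def wls_trend(
    curve: DispersionCurve,
    statistic: Statistic | str,
    alpha: float = 0.05,
) -> TrendResult:
    """Weighted least-squares trend of a binned statistic against age.

    Weights are 1/SE^2 with asymptotic standard errors
    SE(SD) = sd / sqrt(2(n-1)), SE(CV) = cv * sqrt(1/(2(n-1)) + (cv/100)^2/n)
    and SE(MEAN) = sd / sqrt(n); the CI uses the t distribution with
    (bins - 2) degrees of freedom.  If any bin has zero SE (sd = 0) the fit
    falls back to unweighted least squares with a logged warning.
    """
    statistic = Statistic(statistic)
    if len(curve) < 3:
        raise TrendError("trend fit requires >= 3 bins")
    if any(b.n < 2 for b in curve.bins):
        raise TrendError("every bin must contain >= 2 subjects")
    x = curve.midpoints
    y = _statistic_values(curve, statistic)
    se = _bin_standard_errors(curve, statistic)
    X = sm.add_constant(x)
    if np.any(se == 0):
        logger.warning(
            "zero standard error in at least one bin (sd = 0); "
            "falling back to an unweighted least-squares trend fit")
        fit = sm.OLS(y, X).fit()
    else:
        fit = sm.WLS(y, X, weights=1.0 / se ** 2).fit()
    slope = float(fit.params[1])
    ci_low, ci_high = (float(v) for v in fit.conf_int(alpha)[1])
    return TrendResult(statistic=statistic, slope=slope,
                       ci_low=ci_low, ci_high=ci_high,
                       alpha=alpha, method="wls_delta")


# --------------------------------------------------------------------------
# stratified bootstrap
# --------------------------------------------------------------------------

def _ols_slope(x_centred: np.ndarray, y: np.ndarray, sxx: float) -> np.ndarray:
    """Unweighted least-squares slope(s); y may be (n_bins,) or (m, n_bins)."""
    return y @ x_centred / sxx


def bootstrap_trend(
    sample: CohortSample,
    statistic: Statistic | str,
    edges: Sequence[float],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    min_n: int = 10,
) -> TrendResult:
    """Stratified-bootstrap trend of a binned statistic against age.

    Subjects are resampled with replacement *within* each age bin
    (preserving the age design), the binned statistic and its unweighted
    least-squares slope against bin midpoints are recomputed per replicate,
    and the CI is the percentile interval over replicates.  The reported
    slope is the point estimate on the original data.  Replicates on which
    the statistic is undefined (a bin mean <= 0 for COVAR) are redrawn;
    more than 10 % rejected replicates is an error.
    """
    statistic = Statistic(statistic)
    curve = bin_cohort(sample, edges, min_n=min_n)
    x = curve.midpoints
    xc = x - x.mean()
    sxx = float(xc @ xc)
    point = float(_ols_slope(xc, _statistic_values(curve, statistic), sxx))

    ages = sample.data["age"].to_numpy(dtype=float)
    values = sample.data["value"].to_numpy(dtype=float)
    edges_arr = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges_arr, ages, side="right") - 1
    idx[ages == edges_arr[-1]] = edges_arr.size - 2
    bin_values = [values[idx == i] for i in range(edges_arr.size - 1)]

    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    filled = 0
    rejected = 0
    max_rejected = int(0.1 * n_boot)
    while filled < n_boot:
        m = n_boot - filled
        means = np.empty((m, len(bin_values)))
        sds = np.empty((m, len(bin_values)))
        for j, vals in enumerate(bin_values):
            res = vals[rng.integers(0, vals.size, size=(m, vals.size))]
            means[:, j] = res.mean(axis=1)
            sds[:, j] = res.std(axis=1, ddof=1)
        if statistic is Statistic.SD:
            stat = sds
            valid = np.ones(m, dtype=bool)
        elif statistic is Statistic.MEAN:
            stat = means
            valid = np.ones(m, dtype=bool)
        else:
            valid = np.all(means > 0, axis=1)
            stat = np.full_like(means, np.nan)
            stat[valid] = 100.0 * sds[valid] / means[valid]
        rejected += int(m - valid.sum())
        if rejected > max_rejected:
            raise TrendError(
                f"more than 10% of bootstrap replicates ({rejected}/{n_boot}) "
                f"had an undefined {statistic.value} (bin mean <= 0); the "
                "cohort is incompatible with this statistic")
        ok = _ols_slope(xc, stat[valid], sxx)
        slopes[filled:filled + ok.size] = ok
        filled += ok.size
    lo, hi = np.percentile(slopes, [100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0)])
    # the percentile interval may exclude the point estimate in heavily
    # skewed small samples; widen minimally so the result stays coherent
    lo, hi = min(float(lo), point), max(float(hi), point)
    return TrendResult(statistic=statistic, slope=point,
                       ci_low=lo, ci_high=hi, alpha=alpha,
                       method="bootstrap", n_boot=n_boot, seed=seed)
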