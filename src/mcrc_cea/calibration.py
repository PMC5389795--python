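"""Survival-curve calibration: hazards, probabilities and the log-linear fit.

Under a constant hazard, log-survival is linear in time with slope −rate,
so a survival curve is calibrated by ordinary least squares of ln S(t) on
t with the intercept fixed at zero (S(0) = 1 by definition; a free
intercept would imply otherwise and bias short-horizon probabilities).
The fitted yearly rate interconverts with per-cycle probabilities via the
standard constant-hazard relations

    rate = −ln(1 − p) / Δt        p = 1 − exp(−rate · Δt)

which are exact inverses on their domains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import CalibrationError, ValidationError
from .survival import SurvivalSeries

__all__ = [
    "HazardEstimate",
    "prob_to_rate",
    "rate_to_prob",
    "fit_loglinear",
    "series_to_cycle_probability",
]


@dataclass(frozen=True)
class HazardEstimate:
    """A fitted constant hazard (events/year) with regression diagnostics."""

    rate: float
    stderr: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("fitted rate must be non-negative")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise ValidationError("a hazard fit needs at least 2 points")


def prob_to_rate(p: float, interval: float) -> float:
    """Yearly event rate equivalent to probability ``p`` over ``interval`` years."""
    if interval <= 0:
        raise ValidationError("interval must be positive")
    if not 0.0 <= p < 1.0:
        raise ValidationError("probability must lie in [0, 1); p=1 implies an infinite rate")
    return -math.log(1.0 - p) / interval


def rate_to_prob(rate: float, interval: float) -> float:
    """Probability of at least one event over ``interval`` years at ``rate``/year."""
    if interval <= 0:
        raise ValidationError("interval must be positive")
    if rate < 0:
        raise ValidationError("rate must be non-negative")
    return 1.0 - math.exp(-rate * interval)


def fit_loglinear(series: SurvivalSeries) -> HazardEstimate:
    """Fit ln S(t) = −rate · t by OLS through the origin.

    Points with survival exactly 0 are excluded (their log is undefined);
    a warning reports how many were dropped.  The regression is unweighted
    and uses survival fractions only, so it is invariant to any rescaling
    of at-risk counts.
    """
    t = np.asarray(series.times, dtype=float)
    s = np.asarray(series.survival, dtype=float)
    keep = s > 0.0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"excluding {dropped} point(s) with survival 0 from the log-linear fit",
            stacklevel=2,
        )
    t, s = t[keep], s[keep]
    if len(t) < 2:
        raise CalibrationError("need at least 2 points with survival > 0")
    if not np.any(t > 0):
        raise CalibrationError("degenerate design: no positive time point")
    y = np.log(s)
    res = sm.OLS(y, t[:, None]).fit()
    slope = float(res.params[0])
    rate = -slope
    if rate < 0:
        raise CalibrationError(
            "fitted hazard is negative (survival increases with time); "
            "the series is not consistent with an exponential model"
        )
    stderr = float(res.bse[0])
    with np.errstate(invalid="ignore"):
        r2 = float(res.rsquared)
    if math.isnan(r2):
        # all-zero response (survival constant at 1): a zero-residual fit
        r2 = 1.0 if res.ssr < 1e-30 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return HazardEstimate(rate=rate, stderr=stderr, r_squared=r2, n_points=int(len(t)))


def series_to_cycle_probability(series: SurvivalSeries, cycle_length: float) -> float:
    """Per-cycle transition probability implied by a survival series.

    Chains the log-linear fit with the rate→probability conversion at the
    model's cycle length (0.25 years for quarterly cycles).
    """
    estimate = fit_loglinear(series)
    return rate_to_prob(estimate.rate, cycle_length)
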