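"""Fixed-intercept linear trend estimation.

Pool size and fractional labelling of phenylalanine both increase linearly
over the 6-h feeding window, so their rates enter the flux model as slopes of
straight lines.  The intercepts are measured t = 0 values and are held fixed
(not estimated), which leaves a one-parameter least-squares problem:

    b = Σ tᵢ (yᵢ − y₀) / Σ tᵢ²

with residual variance SSR/(n − 1) (one parameter estimated) and slope
variance SSR/(n − 1)/Σ tᵢ².  The cumulative volatile emission series is fit
the same way with intercept 0, giving the constant consumption rate v_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class DegenerateDesignError(ValueError):
    """All sampling times are zero; the slope is unidentifiable."""


class EmissionMonotonicityError(ValueError):
    """Cumulative emission decreases over time (strict mode only)."""


@dataclass(frozen=True)
class LinearTrend:
    """An affine trend y(t) = intercept + slope·t with slope uncertainty.

    ``intercept`` is data, not an estimate, and carries no variance.
    """

    slope: float
    slope_variance: float
    intercept: float
    residual_variance: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.slope_variance < 0 or self.residual_variance < 0:
            raise ValueError("variances must be >= 0")

    def __call__(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def fit_fixed_intercept_slope(
    times, values, intercept: float
) -> LinearTrend:
    """Least-squares slope through a fixed intercept.

    ``times``/``values`` are the post-intercept points; the t = 0 measurement
    enters only as the fixed ``intercept``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and of equal length")
    if t.size < 2:
        raise ValueError("need at least 2 time points to estimate a slope")
    if not np.isfinite(intercept):
        raise ValueError("intercept must be finite")
    st2 = float(t @ t)
    if st2 == 0.0:
        raise DegenerateDesignError("all times are zero")
    slope = float(t @ (y - intercept)) / st2
    resid = y - intercept - slope * t
    ssr = float(resid @ resid)
    residual_variance = ssr / (t.size - 1)
    return LinearTrend(
        slope=slope,
        slope_variance=residual_variance / st2,
        intercept=float(intercept),
        residual_variance=residual_variance,
        n_points=int(t.size),
    )


def evaluate_trend(trend: LinearTrend, grid) -> np.ndarray:
    """Evaluate the affine trend on a time grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid is empty")
    return trend.intercept + trend.slope * grid


def mean_tyrosine_labelling(series) -> tuple[float, float]:
    """Average tyrosine ¹⁵N fraction over the experiment.

    Tyrosine labelling plateaus above 0.8 within ~2 h of feeding, so its
    post-feeding observations are summarised by the arithmetic mean.  Returns
    ``(mean, variance_of_the_mean)`` with the variance of the mean computed
    as sample variance / n (0 for a single observation).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty tyrosine labelling series")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("tyrosine fractions must lie in [0, 1]")
    mean = float(x.mean())
    var_mean = float(x.var(ddof=1) / x.size) if x.size > 1 else 0.0
    return mean, var_mean


def estimate_consumption_rate(
    emission_times, cumulative_emission, strict: bool = False
) -> LinearTrend:
    """Constant phenylalanine consumption rate v_c from cumulative emission.

    Fixed-intercept fit through 0 at the start of volatile collection.  A
    decreasing cumulative series is physically impossible but can arise from
    measurement noise; by default it only warns, ``strict=True`` raises.
    """
    t = np.asarray(emission_times, dtype=float)
    y = np.asarray(cumulative_emission, dtype=float)
    order = np.argsort(t)
    if np.any(np.diff(y[order]) < 0):
        msg = "cumulative emission decreases over time"
        if strict:
            raise EmissionMonotonicityError(msg)
        warnings.warn(msg, stacklevel=2)
    return fit_fixed_intercept_slope(t, y, intercept=0.0)
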