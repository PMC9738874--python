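"""Morphometry: ellipsoid renal volumetry, growth rates and dose arithmetic.

Kidney volumes are estimated from three orthogonal MRI axis lengths with the
ellipsoid approximation V = (pi/6) L W D (full axes, hence pi/6 rather than
the semi-axis form 4*pi/3 * abc).  Body-weight growth rate is the OLS slope
of ln(weight) on postnatal day (an exponential-growth rate, per day), and a
reference growth trajectory is synthesised by fitting a 4-parameter logistic
to five anchor points.  The cumulative chemotherapy dose of a fixed regimen
is the product dose_per_administration x administrations_per_week x weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, InvalidParameterError

__all__ = [
    "KidneyAxes",
    "GrowthSeries",
    "SigmoidGrowth",
    "ellipsoid_volume",
    "growth_rate",
    "sigmoid_reference",
    "cumulative_dose",
]


@dataclass(frozen=True)
class KidneyAxes:
    """Full orthogonal axis lengths of a kidney (mm)."""

    length: float
    width: float
    depth: float

    def __post_init__(self) -> None:
        if not all(v > 0 and math.isfinite(v) for v in (self.length, self.width, self.depth)):
            raise InvalidParameterError("all axes must be positive and finite")


@dataclass(frozen=True)
class GrowthSeries:
    """Body weights (g) against postnatal days."""

    postnatal_day: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        day = np.asarray(self.postnatal_day, float)
        w = np.asarray(self.weight, float)
        object.__setattr__(self, "postnatal_day", day)
        object.__setattr__(self, "weight", w)
        if day.size != w.size or day.size < 2:
            raise InsufficientDataError("need >= 2 (day, weight) pairs of equal length")
        if np.any(np.diff(day) <= 0):
            raise InvalidParameterError("days must be strictly increasing")
        if np.any(w <= 0):
            raise InvalidParameterError("weights must be positive")


@dataclass(frozen=True)
class SigmoidGrowth:
    """4-parameter logistic growth curve w(t) = a + (b-a)/(1+exp(-c(t-t0)))."""

    a: float
    b: float
    c: float
    t0: float

    def __call__(self, t) -> np.ndarray:
        t_arr = np.asarray(t, float)
        out = self.a + (self.b - self.a) / (1.0 + np.exp(-self.c * (t_arr - self.t0)))
        return out if out.ndim else float(out)


def ellipsoid_volume(axes: KidneyAxes) -> float:
    """Ellipsoid volume (mm^3) from full axis lengths: (pi/6) L W D."""
    return math.pi / 6.0 * axes.length * axes.width * axes.depth


def growth_rate(series: GrowthSeries) -> float:
    """Exponential growth rate (per day): OLS slope of ln(weight) on day."""
    slope, _ = np.polyfit(series.postnatal_day, np.log(series.weight), 1)
    return float(slope)


def sigmoid_reference(anchor_days, anchor_weights) -> SigmoidGrowth:
    """Fit a 4-parameter logistic through five (day, weight) anchor points.

    Bounds keep the fit identifiable and physical for monotone anchors: the
    lower asymptote cannot exceed the smallest anchor, the upper cannot fall
    below the largest, and the steepness is non-negative, so the returned
    curve is monotone non-decreasing.
    """
    days = np.asarray(anchor_days, float)
    weights = np.asarray(anchor_weights, float)
    if days.size != 5 or weights.size != 5:
        raise InvalidParameterError("exactly 5 anchor points are required")
    if np.any(np.diff(days) <= 0):
        raise InvalidParameterError("anchor days must be strictly increasing")
    if np.ptp(weights) == 0:
        raise FitError("anchors are degenerate (all weights equal)")

    w_lo, w_hi = float(np.min(weights)), float(np.max(weights))
    span = float(np.ptp(days))
    p0 = [w_lo, w_hi, 4.0 / span, float(np.median(days))]
    # asymptotes must bracket the anchors and the steepness stay non-negative;
    # beyond that the fit is free (extrapolated asymptotes may be unphysical)
    bounds = (
        [-np.inf, w_hi, 0.0, days[0] - span],
        [w_lo, np.inf, np.inf, days[-1] + span],
    )

    def model(t, a, b, c, t0):
        return a + (b - a) / (1.0 + np.exp(-c * (t - t0)))

    try:
        popt, _ = curve_fit(model, days, weights, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"logistic fit failed: {exc}") from exc
    return SigmoidGrowth(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), t0=float(popt[3]))


def cumulative_dose(dose_per_admin: float, admins_per_week: float, weeks: float) -> float:
    """Cumulative dose (mg/kg) of a fixed repeated-administration regimen."""
    if dose_per_admin < 0 or admins_per_week < 0 or weeks < 0:
        raise InvalidParameterError("regimen inputs must be non-negative")
    return float(dose_per_admin) * float(admins_per_week) * float(weeks)
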