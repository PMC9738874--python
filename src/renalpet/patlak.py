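"""Patlak graphical analysis and the early renal slope markers.

For an irreversibly trapped tracer the Patlak transform plots

    y(t) = C_T(t)/Cp(t)   against   x(t) = int_0^t Cp(s) ds / Cp(t)

and, once the free compartment equilibrates with plasma, the points fall on a
line whose slope is the net influx rate Ki.  The renal markers used here
deliberately regress *early* segments of the same coordinates, where the
equilibrium assumption does not hold: over the first ~9 s of tissue activity
the cortical/medullary slope is an empirical vascular-transit analog, and
over ~60-120 s after tracer arrival the pelvic slope tracks the ramp-up of
urinary excretion (an extraction marker).  The liver's long early linear
segment serves as a per-group control.  Slopes are reported per minute.

Blood-curve quality control implements the tail-depot exclusion rule: a
persistently ascending aorta curve that never flattens betrays tracer trapped
at the injection site and invalidates every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError
from .frames import TimeActivityCurve

__all__ = [
    "PatlakPoints",
    "LinearWindow",
    "PatlakMarker",
    "QcResult",
    "patlak_transform",
    "first_nonzero_frame",
    "prescribed_window",
    "detect_linear_segment",
    "fit_slope",
    "age_control_ratio",
    "peak_amplitude_ratio",
    "qc_blood_curve",
]

#: early-window offsets (start, end) in seconds relative to tracer arrival t0.
#: Cortex/medulla: first ~9 s of tissue activity (vascular transit analog).
#: Pelvis: 60-120 s after arrival (urinary extraction ramp).  Liver: the long
#: early linear rise, ending 5 s before its nominal ~60 s peak.
REGION_WINDOW_OFFSETS: dict[str, tuple[float, float]] = {
    "cortex": (0.0, 9.0),
    "medulla": (0.0, 9.0),
    "pelvis": (60.0, 120.0),
    "liver": (0.0, 55.0),
}

DEFAULT_QC_FLATNESS_CEILING = 0.10


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak coordinates with provenance back to the framing schedule."""

    x: np.ndarray           # normalized time int Cp / Cp (s)
    y: np.ndarray           # C_T/Cp (dimensionless)
    t: np.ndarray           # frame mid-times (s) the points came from
    frame_index: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "t"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        object.__setattr__(self, "frame_index", np.asarray(self.frame_index, int))
        n = self.x.size
        if any(getattr(self, name).size != n for name in ("y", "t", "frame_index")):
            raise InvalidParameterError("coordinate arrays must have equal length")
        if np.any(self.x < 0):
            raise InvalidParameterError("normalized time must be non-negative")

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class LinearWindow:
    """A time window [t_start, t_end] (s) over which a slope is regressed."""

    t_start: float
    t_end: float
    n_points: int | None = None

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start):
            raise InvalidParameterError("window needs t_end > t_start")
        if self.n_points is not None and self.n_points < 3:
            raise InvalidParameterError("a regression window needs >= 3 points")


@dataclass(frozen=True)
class PatlakMarker:
    """Slope marker of one region over one linearity window."""

    region: str
    slope_per_min: float
    intercept: float
    r_squared: float
    window: LinearWindow

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_per_min):
            raise InvalidParameterError("slope must be finite")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise InvalidParameterError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class QcResult:
    """Outcome of the blood-curve tail-depot screen."""

    passed: bool
    flatness_index: float
    reason: str = ""


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares; returns (slope, intercept, r_squared).

    A window of identical y values is a perfect horizontal line (R^2 = 1).
    """
    slope, intercept = np.polyfit(x, y, 1)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return float(slope), float(intercept), 1.0
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    return float(slope), float(intercept), max(0.0, 1.0 - ss_res / ss_tot)


def patlak_transform(
    tissue: TimeActivityCurve,
    input_tac: TimeActivityCurve,
    threshold_frac: float = 0.01,
) -> PatlakPoints:
    """Patlak coordinates of a tissue curve against the plasma curve.

    The cumulative plasma integral is a trapezoid over frame mid-times with a
    constant lead-in from t=0 (exact for a constant input; negligible for a
    bolus whose pre-arrival frames are zero).  Points are emitted only where
    Cp exceeds ``threshold_frac`` of its peak, so near-zero denominators never
    enter the regression.
    """
    if not tissue.schedule.same_as(input_tac.schedule):
        raise InvalidParameterError("tissue and input curves must share one schedule")
    cp = input_tac.values
    peak = float(np.max(cp))
    if peak <= 0:
        raise DegenerateInputError("input curve has no positive activity")
    mids = input_tac.schedule.mid
    cum = cp[0] * (mids[0] - input_tac.schedule.start[0]) + cumulative_trapezoid(
        cp, mids, initial=0.0
    )
    mask = cp > threshold_frac * peak
    if not np.any(mask):
        raise DegenerateInputError("input curve entirely below the Patlak threshold")
    return PatlakPoints(
        x=cum[mask] / cp[mask],
        y=tissue.values[mask] / cp[mask],
        t=mids[mask],
        frame_index=np.nonzero(mask)[0],
    )


def first_nonzero_frame(tac: TimeActivityCurve, threshold_frac: float = 0.02) -> int:
    """Index of the first frame above ``threshold_frac`` of the curve peak.

    The default 2% threshold makes "first non-zero" robust on noisy 1 s
    frames, where strictly positive reconstruction noise precedes the bolus.
    """
    if threshold_frac < 0:
        raise InvalidParameterError("threshold_frac must be non-negative")
    peak = tac.peak
    if peak <= 0:
        raise DegenerateInputError("curve has no positive activity")
    above = tac.values > threshold_frac * peak
    return int(np.argmax(above))


def prescribed_window(
    region: str, t0: float, t_support_end: float | None = None
) -> LinearWindow:
    """The region's fixed early-linearity window anchored at tracer arrival t0.

    Cortex/medulla: [t0, t0+9] s; pelvis: [t0+60, t0+120] s; liver:
    [t0, t0+55] s.  The window is clipped to the curve support when
    ``t_support_end`` is given.
    """
    try:
        off0, off1 = REGION_WINDOW_OFFSETS[region]
    except KeyError:
        raise InvalidParameterError(
            f"unknown region {region!r}; expected one of {sorted(REGION_WINDOW_OFFSETS)}"
        ) from None
    t_start, t_end = t0 + off0, t0 + off1
    if t_support_end is not None:
        t_end = min(t_end, t_support_end)
        if t_end <= t_start:
            raise InvalidParameterError("window lies outside the curve support")
    return LinearWindow(t_start=t_start, t_end=t_end)


def detect_linear_segment(
    points: PatlakPoints, min_points: int = 5, r2_min: float = 0.95
) -> LinearWindow | None:
    """Longest contiguous run of points whose OLS fit keeps R^2 >= ``r2_min``.

    Expanding-window scan from every candidate start (ties broken toward the
    earlier start); returns ``None`` when no run of ``min_points`` qualifies,
    so callers can fall back to the prescribed windows.
    """
    n = len(points)
    if min_points < 3:
        raise InvalidParameterError("min_points must be >= 3")
    if n < min_points:
        raise InsufficientDataError(f"need at least {min_points} points")
    x, y = points.x, points.y
    # prefix sums give O(1) window statistics for the O(n^2) scan
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])

    def r2(i: int, j: int) -> float:  # window [i, j] inclusive
        m = j - i + 1
        sx = cx[j + 1] - cx[i]
        sy = cy[j + 1] - cy[i]
        sxx = (cxx[j + 1] - cxx[i]) - sx * sx / m
        syy = (cyy[j + 1] - cyy[i]) - sy * sy / m
        sxy = (cxy[j + 1] - cxy[i]) - sx * sy / m
        if syy <= 0.0:
            return 1.0
        if sxx <= 0.0:
            return 0.0
        return min(1.0, (sxy * sxy) / (sxx * syy))

    best_len, best_span = 0, None
    for i in range(n - min_points + 1):
        for j in range(i + min_points - 1, n):
            if j - i + 1 > best_len and r2(i, j) >= r2_min:
                best_len, best_span = j - i + 1, (i, j)
    if best_span is None:
        return None
    i, j = best_span
    return LinearWindow(t_start=float(points.t[i]), t_end=float(points.t[j]), n_points=best_len)


def fit_slope(points: PatlakPoints, window: LinearWindow, region: str = "") -> PatlakMarker:
    """OLS slope of the Patlak points inside a time window, reported per minute."""
    sel = (points.t >= window.t_start - 1e-9) & (points.t <= window.t_end + 1e-9)
    if int(np.sum(sel)) < 3:
        raise InsufficientDataError("need >= 3 Patlak points inside the window")
    slope_per_s, intercept, r2 = _ols(points.x[sel], points.y[sel])
    return PatlakMarker(
        region=region,
        slope_per_min=slope_per_s * 60.0,
        intercept=intercept,
        r_squared=min(r2, 1.0),
        window=LinearWindow(window.t_start, window.t_end, n_points=int(np.sum(sel))),
    )


def age_control_ratio(marker_value: float, control_mean: float) -> float:
    """A group marker divided by the mean of its age-matched control group."""
    if not control_mean > 0:
        raise InvalidParameterError("control_mean must be positive")
    return marker_value / control_mean


def peak_amplitude_ratio(
    cortex: TimeActivityCurve,
    medulla: TimeActivityCurve,
    search_window: LinearWindow,
) -> float:
    """max(cortex)/max(medulla) within the early vascular window.

    In healthy animals the medullary transit peak is about twice the cortical
    one, so this ratio sits near 0.5 and drifts up as cortical uptake decays.
    """
    for tac in (cortex, medulla):
        if not np.any(tac.values > 0):
            raise DegenerateInputError("curve has no positive activity")
    mids = cortex.schedule.mid
    sel = (mids >= search_window.t_start) & (mids <= search_window.t_end)
    if not np.any(sel):
        raise InsufficientDataError("no frames inside the search window")
    med_peak = float(np.max(medulla.values[sel]))
    if med_peak <= 0:
        raise DegenerateInputError("medullary peak is zero inside the window")
    return float(np.max(cortex.values[sel])) / med_peak


def qc_blood_curve(
    blood: TimeActivityCurve,
    flatness_ceiling: float = DEFAULT_QC_FLATNESS_CEILING,
    threshold_frac: float = 0.02,
) -> QcResult:
    """Screen the vascular curve for the tail-depot injection artifact.

    A clean bolus rises steeply, peaks within minutes and then decays.  The
    flatness index compares the OLS slope over the terminal third of the scan
    with the slope of the rise phase (first supra-threshold frame to peak);
    the curve fails when the index exceeds ``flatness_ceiling`` or when the
    global maximum falls in the terminal third - both signatures of tracer
    slowly leaking from a tail-vein depot instead of a bolus transit.
    """
    v = blood.values
    if not np.any(v > 0):
        raise DegenerateInputError("blood curve has no positive activity")
    mids = blood.schedule.mid
    t_lo, t_hi = blood.schedule.start[0], blood.schedule.end[-1]
    tail_from = t_lo + 2.0 / 3.0 * (t_hi - t_lo)

    i0 = first_nonzero_frame(blood, threshold_frac)
    ipk = int(np.argmax(v))

    tail_sel = mids >= tail_from
    rise_sel = np.zeros_like(tail_sel)
    rise_sel[i0 : ipk + 1] = True

    flatness = np.nan
    if np.sum(rise_sel) >= 2 and np.sum(tail_sel) >= 2:
        rise_slope, _, _ = _ols(mids[rise_sel], v[rise_sel])
        tail_slope, _, _ = _ols(mids[tail_sel], v[tail_sel])
        flatness = tail_slope / rise_slope if rise_slope > 0 else np.inf

    if mids[ipk] >= tail_from:
        return QcResult(passed=False, flatness_index=float(flatness), reason="tail depot")
    if np.sum(rise_sel) < 2:
        return QcResult(passed=False, flatness_index=float(flatness), reason="no distinct rise phase")
    if not np.isfinite(flatness) or flatness > flatness_ceiling:
        return QcResult(passed=False, flatness_index=float(flatness), reason="tail depot")
    return QcResult(passed=True, flatness_index=float(flatness))
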