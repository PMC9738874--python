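"""Static-frame SUV analysis.

The 40-min dynamic acquisition is partitioned into three static windows:
TP1 = 0-5 min (perfusion-dominated), TP2 = 15-20 min (intermediate) and
TP3 = 35-40 min (uptake-dominated).  Each region's window mean is converted
to a standardized uptake value SUV = C / (dose/weight) (tissue density taken
as 1 g/mL, body weight as the normalisation mass), then normalised to the
blood (aorta) mean over the same window.  The renal output proxy is the
pelvis window mean divided by the cortical one: a functioning kidney moves
tracer from cortex to pelvis, so a blunted ratio flags failing excretion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError
from .frames import TimeActivityCurve

__all__ = [
    "StaticWindow",
    "SuvValue",
    "TP1",
    "TP2",
    "TP3",
    "STATIC_WINDOWS",
    "suv",
    "window_mean",
    "blood_normalized",
    "renal_output_marker",
]


@dataclass(frozen=True)
class StaticWindow:
    """A labelled static reconstruction window [t_start, t_end] in seconds."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start):
            raise InvalidParameterError("window needs t_end > t_start")


# single source of truth for the static windows, shared with the pipeline
TP1 = StaticWindow("TP1", 0.0, 300.0)
TP2 = StaticWindow("TP2", 900.0, 1200.0)
TP3 = StaticWindow("TP3", 2100.0, 2400.0)
STATIC_WINDOWS: tuple[StaticWindow, ...] = (TP1, TP2, TP3)


@dataclass(frozen=True)
class SuvValue:
    """SUV of one region over one static window, raw and blood-normalised."""

    region: str
    window: StaticWindow
    suv: float
    suv_blood_norm: float

    def __post_init__(self) -> None:
        if self.suv < 0 or self.suv_blood_norm < 0:
            raise InvalidParameterError("SUV values must be non-negative")


def suv(conc_kbq_ml: float, dose_mbq: float, weight_g: float) -> float:
    """Standardized uptake value: concentration over injected dose per gram.

    ``conc/(1000*dose/weight)`` - the factor 1000 converts MBq to kBq so the
    result is dimensionless for a tissue density of 1 g/mL.
    """
    if dose_mbq <= 0:
        raise InvalidParameterError("dose must be positive")
    if weight_g <= 0:
        raise InvalidParameterError("weight must be positive")
    return float(conc_kbq_ml) / (1000.0 * dose_mbq / weight_g)


def window_mean(tac: TimeActivityCurve, w: StaticWindow) -> float:
    """Duration-weighted mean concentration over the window.

    Frames partially overlapping the window contribute pro-rata by their
    overlap duration - the framed-data equivalent of reconstructing a static
    frame over the window.
    """
    overlap = np.minimum(tac.schedule.end, w.t_end) - np.maximum(tac.schedule.start, w.t_start)
    overlap = np.clip(overlap, 0.0, None)
    total = float(np.sum(overlap))
    if total <= 0:
        raise InsufficientDataError(f"no frames overlap window {w.label} [{w.t_start}, {w.t_end}] s")
    return float(np.sum(tac.values * overlap) / total)


def blood_normalized(region_mean: float, blood_mean: float) -> float:
    """Region concentration divided by the blood-pool concentration."""
    if not blood_mean > 0:
        raise InvalidParameterError("blood mean must be positive")
    return float(region_mean) / float(blood_mean)


def renal_output_marker(
    pelvis: TimeActivityCurve, cortex: TimeActivityCurve, w: StaticWindow
) -> float:
    """Pelvis-to-cortex concentration ratio over a static window.

    Proxy for renal output: the rate at which filtered tracer accumulates in
    the collecting system relative to the parenchyma that feeds it.
    """
    cortex_mean = window_mean(cortex, w)
    if cortex_mean <= 0:
        raise DegenerateInputError("cortical window mean is zero")
    return window_mean(pelvis, w) / cortex_mean
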