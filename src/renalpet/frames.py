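"""Framing schedules and time-activity curves.

A dynamic PET acquisition is partitioned into contiguous time frames; every
curve in the package is a vector of frame-averaged activity concentrations
(kBq/mL) on such a schedule.  The default preclinical protocol samples the
first 5 min at 1 s per frame (catching the bolus transit), the next 15 min at
10 s and the final 20 min at 30 s, i.e. 300 + 90 + 40 = 430 frames over
40 min.  Time is carried in seconds everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "FramingSchedule",
    "TimeActivityCurve",
    "dynamic_framing_schedule",
]


@dataclass(frozen=True)
class FramingSchedule:
    """Ordered, contiguous, half-open frame intervals ``[start, end)`` in seconds."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise InvalidParameterError("start/end must be equal-length 1-D arrays")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise InvalidParameterError("frame times must be finite")
        if start[0] < 0:
            raise InvalidParameterError("schedule must not start before t=0")
        if not np.all(end > start):
            raise InvalidParameterError("every frame must have end > start")
        if not np.allclose(start[1:], end[:-1]):
            raise InvalidParameterError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_epochs(cls, epochs: Iterable[tuple[int, float]], t0: float = 0.0) -> "FramingSchedule":
        """Build a schedule from ``(n_frames, frame_duration_s)`` epochs."""
        edges = [float(t0)]
        for n, dt in epochs:
            if n < 0 or dt <= 0:
                raise InvalidParameterError("epochs need n >= 0 and duration > 0")
            base = edges[-1]
            edges.extend(base + dt * (i + 1) for i in range(int(n)))
        edges_arr = np.asarray(edges)
        return cls(start=edges_arr[:-1], end=edges_arr[1:])

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def duration(self) -> np.ndarray:
        """Per-frame duration (s)."""
        return self.end - self.start

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times (s)."""
        return 0.5 * (self.start + self.end)

    @property
    def total_duration(self) -> float:
        return float(self.end[-1] - self.start[0])

    def refined(self, max_step: float) -> tuple[np.ndarray, np.ndarray]:
        """Subdivide every frame into sub-intervals no longer than ``max_step``.

        Returns ``(nodes, frame_of_interval)`` where ``nodes`` contains every
        frame boundary plus uniform interior points, and ``frame_of_interval``
        maps each of the ``len(nodes) - 1`` intervals to its frame index.
        Quantities integrated per sub-interval can then be aggregated per
        frame with ``np.add.reduceat`` / ``np.bincount``.
        """
        if max_step <= 0:
            raise InvalidParameterError("max_step must be positive")
        pieces = [np.array([self.start[0]])]
        counts = np.empty(self.n_frames, dtype=int)
        for k in range(self.n_frames):
            n_sub = max(1, int(np.ceil((self.end[k] - self.start[k]) / max_step)))
            counts[k] = n_sub
            pieces.append(np.linspace(self.start[k], self.end[k], n_sub + 1)[1:])
        nodes = np.concatenate(pieces)
        frame_of_interval = np.repeat(np.arange(self.n_frames), counts)
        return nodes, frame_of_interval

    def same_as(self, other: "FramingSchedule", tol: float = 1e-9) -> bool:
        return (
            self.n_frames == other.n_frames
            and np.allclose(self.start, other.start, atol=tol)
            and np.allclose(self.end, other.end, atol=tol)
        )


def dynamic_framing_schedule() -> FramingSchedule:
    """The default 40-min dynamic protocol: 300x1 s, 90x10 s, 40x30 s (430 frames)."""
    return FramingSchedule.from_epochs([(300, 1.0), (90, 10.0), (40, 30.0)])


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/mL) of one region."""

    schedule: FramingSchedule
    values: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise InvalidParameterError("values must match the schedule frame count")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("activity values must be finite")

    def __len__(self) -> int:
        return self.schedule.n_frames

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    def with_values(self, values: Sequence[float]) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, np.asarray(values, float), self.region)
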