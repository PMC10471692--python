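"""Domain types: gaze traces, trial metadata, and oculomotor events."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional, Union

import numpy as np

from .geometry import ScreenGeometry, px_to_deg

__all__ = [
    "AOIRect",
    "BlinkEvent",
    "EventSequence",
    "FixationEvent",
    "GazeSample",
    "GazeTrace",
    "SaccadeEvent",
    "TrialRecord",
]

Side = Literal["left", "right"]
Orientation = Literal["normal", "mirrored"]


@dataclass(frozen=True)
class AOIRect:
    """Half-open pixel rectangle [x0, x1) x [y0, y1) around the target."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("degenerate AOI rectangle")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def mirrored(self, width_px: float) -> "AOIRect":
        return AOIRect(width_px - self.x1, self.y0, width_px - self.x0, self.y1)


@dataclass(frozen=True)
class GazeSample:
    """One binocular sample; invalid eyes carry NaN positions."""

    t: int
    x_left: float
    y_left: float
    x_right: float
    y_right: float
    valid_left: bool
    valid_right: bool


@dataclass
class GazeTrace:
    """A trial's 1 kHz binocular raw-gaze record as column arrays.

    ``t`` is milliseconds since scene onset (negative during the pre-scene
    fixation) and strictly increases in steps of 1 ms. Invalid samples hold
    NaN positions and a False validity flag.
    """

    t: np.ndarray
    x_left: np.ndarray
    y_left: np.ndarray
    x_right: np.ndarray
    y_right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x_left", "y_left", "x_right", "y_right",
                     "valid_left", "valid_right"):
            if len(getattr(self, name)) != n:
                raise ValueError("gaze trace arrays must share one length")
        if n > 1 and not np.all(np.diff(self.t) == 1):
            raise ValueError("gaze samples must increase in steps of 1 ms")

    def __len__(self) -> int:
        return len(self.t)

    def samples(self) -> Iterator[GazeSample]:
        for i in range(len(self)):
            yield GazeSample(
                int(self.t[i]),
                float(self.x_left[i]), float(self.y_left[i]),
                float(self.x_right[i]), float(self.y_right[i]),
                bool(self.valid_left[i]), bool(self.valid_right[i]),
            )

    @property
    def both_valid(self) -> np.ndarray:
        return self.valid_left & self.valid_right

    def binocular_x(self) -> np.ndarray:
        """Average-of-eyes horizontal position; NaN unless both eyes valid."""
        x = np.full(len(self), np.nan)
        ok = self.both_valid
        x[ok] = 0.5 * (self.x_left[ok] + self.x_right[ok])
        return x

    def eye_positions(self, eye: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, valid) arrays for 'left', 'right' or 'average' eye."""
        if eye == "left":
            return self.x_left, self.y_left, self.valid_left
        if eye == "right":
            return self.x_right, self.y_right, self.valid_right
        if eye == "average":
            ok = self.both_valid
            x = np.full(len(self), np.nan)
            y = np.full(len(self), np.nan)
            x[ok] = 0.5 * (self.x_left[ok] + self.x_right[ok])
            y[ok] = 0.5 * (self.y_left[ok] + self.y_right[ok])
            return x, y, ok
        raise ValueError(f"unknown eye {eye!r}")

    def mirrored(self, geometry: ScreenGeometry) -> "GazeTrace":
        w = float(geometry.width_px)
        return GazeTrace(
            t=self.t.copy(),
            x_left=w - self.x_left,
            y_left=self.y_left.copy(),
            x_right=w - self.x_right,
            y_right=self.y_right.copy(),
            valid_left=self.valid_left.copy(),
            valid_right=self.valid_right.copy(),
        )


@dataclass
class TrialRecord:
    """Design cell, AOI geometry, response and timing of one trial."""

    subject_id: str
    scene_id: str
    target_side: Side
    orientation: Orientation
    aoi: AOIRect
    target_center: tuple[float, float]  # pixels
    response_time_ms: Optional[int] = None
    timed_out: bool = False
    correct: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.timed_out != (self.response_time_ms is None):
            raise ValueError("timed_out must be true iff response_time_ms absent")
        if self.response_time_ms is not None and self.response_time_ms > 15000:
            raise ValueError("response_time_ms exceeds the 15 s timeout")
        cx, cy = self.target_center
        if not self.aoi.contains(cx, cy):
            raise ValueError("AOI must contain the target centre")

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.scene_id)

    def mirrored(self, geometry: ScreenGeometry) -> "TrialRecord":
        w = float(geometry.width_px)
        cx, cy = self.target_center
        return replace(
            self,
            target_side="left" if self.target_side == "right" else "right",
            orientation="mirrored" if self.orientation == "normal" else "normal",
            aoi=self.aoi.mirrored(w),
            target_center=(w - cx, cy),
        )


@dataclass
class FixationEvent:
    ordinal: int
    t_start: int
    t_end: int
    x: float
    y: float
    blink_adjacent: bool = False
    offscreen: bool = False

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")


@dataclass
class SaccadeEvent:
    ordinal: int
    t_start: int
    t_end: int
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    amplitude: float  # degrees
    direction: float  # degrees in [0, 360)
    blink_adjacent: bool = False

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("saccade amplitude must be non-negative")
        if not (0.0 <= self.direction < 360.0):
            raise ValueError("saccade direction must lie in [0, 360)")


@dataclass
class BlinkEvent:
    t_start: int
    t_end: int

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start


Event = Union[FixationEvent, SaccadeEvent, BlinkEvent]


@dataclass
class EventSequence:
    """Time-ordered fixations, saccades and blinks of one trial."""

    events: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def fixations(self) -> list:
        return [e for e in self.events if isinstance(e, FixationEvent)]

    @property
    def saccades(self) -> list:
        return [e for e in self.events if isinstance(e, SaccadeEvent)]

    @property
    def blinks(self) -> list:
        return [e for e in self.events if isinstance(e, BlinkEvent)]

    def counts(self) -> tuple[int, int, int]:
        return len(self.fixations), len(self.saccades), len(self.blinks)


def saccade_metrics(x_start: float, y_start: float, x_end: float, y_end: float,
                    geometry: ScreenGeometry) -> tuple[float, float]:
    """(amplitude_deg, direction_deg) of the start -> end chord in pixels."""
    x0, y0 = px_to_deg(x_start, y_start, geometry)
    x1, y1 = px_to_deg(x_end, y_end, geometry)
    dx, dy = float(x1 - x0), float(y1 - y0)
    amp = math.hypot(dx, dy)
    if amp == 0.0:
        return 0.0, 0.0
    ang = math.degrees(math.atan2(dy, dx)) % 360.0
    return amp, ang
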