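"""First-saccade direction analyses: eligibility, angles, polar histograms.

The initial eye movement of each trial is analysed only when it exceeds a
minimum amplitude (1 deg) and was launched from within the scene's central
region; trials whose first saccade fails either test contribute no
observation (no fallback to later saccades). Directions use the degree
frame: 0 deg = rightward, 90 deg = upward. A saccade is leftward when its
angle is strictly between 90 and 270 deg, rightward when strictly below 90
or strictly above 270; the exact boundaries are undefined and excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import ScreenGeometry, px_to_deg
from .types import EventSequence, SaccadeEvent

__all__ = [
    "PolarHistogram",
    "first_saccade",
    "direction_angle",
    "dichotomize_direction",
    "polar_histogram",
]


def first_saccade(events: EventSequence, geometry: ScreenGeometry,
                  min_amplitude_deg: float = 1.0,
                  central_radius_deg: float = 1.93) -> Optional[SaccadeEvent]:
    """The trial's eligible first saccade, or None.

    Eligible means: it is the chronologically first saccade after scene
    onset, its amplitude exceeds ``min_amplitude_deg``, and its start point
    lies within ``central_radius_deg`` of the screen centre.
    """
    post = [s for s in events.saccades if s.t_start >= 0]
    if not post:
        return None
    first = min(post, key=lambda s: s.t_start)
    if first.amplitude <= min_amplitude_deg:
        return None
    sx, sy = px_to_deg(first.x_start, first.y_start, geometry)
    if math.hypot(float(sx), float(sy)) > central_radius_deg:
        return None
    return first


def direction_angle(saccade: SaccadeEvent) -> float:
    """Angle of the start -> end line in [0, 360); 180 deg = leftward."""
    if saccade.amplitude == 0:
        raise ValueError("direction of a zero-length saccade is undefined")
    return saccade.direction


def dichotomize_direction(angle_deg: float) -> str:
    """'left' (> 90 and < 270), 'right' (< 90 or > 270), else 'undefined'."""
    a = angle_deg % 360.0
    if 90.0 < a < 270.0:
        return "left"
    if a < 90.0 or a > 270.0:
        return "right"
    return "undefined"


@dataclass(frozen=True)
class PolarHistogram:
    """Density histogram of saccade directions.

    Densities are per degree: ``sum(densities) * bin_width_deg == 1``, so
    values are comparable across bin widths.
    """

    bin_centers: np.ndarray
    densities: np.ndarray
    n: int

    @property
    def n_bins(self) -> int:
        return len(self.densities)

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / self.n_bins

    def left_mass(self) -> float:
        """Probability mass over directions in (90, 270)."""
        lo = np.searchsorted(self.bin_centers - self.bin_width_deg / 2, 90.0)
        hi = np.searchsorted(self.bin_centers - self.bin_width_deg / 2, 270.0)
        return float(np.sum(self.densities[lo:hi]) * self.bin_width_deg)


def polar_histogram(angles_deg, n_bins: int = 36) -> PolarHistogram:
    """Bin direction angles into ``n_bins`` equal bins of [k*w, (k+1)*w)."""
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    if angles.size == 0:
        raise ValueError("cannot build a polar histogram from no angles")
    width = 360.0 / n_bins
    counts, _ = np.histogram(angles, bins=np.arange(0.0, 360.0 + width / 2, width))
    densities = counts / (angles.size * width)
    centers = (np.arange(n_bins) + 0.5) * width
    return PolarHistogram(bin_centers=centers, densities=densities,
                          n=int(angles.size))
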