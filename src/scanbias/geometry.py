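"""Screen geometry and pixel <-> visual-angle conversions.

Two coordinate frames are used throughout the package:

* **pixel frame** — origin at the top-left screen corner, x rightward,
  y *downward* (the usual screen/tracker convention);
* **degree frame** — origin at the screen centre, x rightward, y *upward*,
  in degrees of visual angle, so that a saccade direction of 90 deg means
  upward and the "lower quadrants" are directions in (180, 360).

The mapping is linear and anisotropic: horizontal and vertical px/deg
factors are computed independently from the stated subtenses (they differ
slightly for a non-square pixel raster), and amplitudes are Euclidean norms
in degree space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry", "px_to_deg", "deg_to_px"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry of the experiment.

    Defaults describe an 800 x 600 px scene subtending 25.78 x 19.34 deg
    of visual angle at 90 cm viewing distance.
    """

    width_px: int = 800
    height_px: int = 600
    width_deg: float = 25.78
    height_deg: float = 19.34
    viewing_distance_cm: float = 90.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen size in pixels must be positive")
        if self.width_deg <= 0 or self.height_deg <= 0:
            raise ValueError("screen size in degrees must be positive")
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing distance must be positive")

    @property
    def center_px(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0

    @property
    def deg_per_px_x(self) -> float:
        return self.width_deg / self.width_px

    @property
    def deg_per_px_y(self) -> float:
        return self.height_deg / self.height_px


def px_to_deg(x_px, y_px, geometry: ScreenGeometry):
    """Convert pixel coordinates to degrees relative to screen centre.

    Accepts scalars or arrays. The y axis is flipped: positive y in the
    degree frame points upward.
    """
    cx, cy = geometry.center_px
    x_deg = (np.asarray(x_px, dtype=float) - cx) * geometry.deg_per_px_x
    y_deg = (cy - np.asarray(y_px, dtype=float)) * geometry.deg_per_px_y
    return x_deg, y_deg


def deg_to_px(x_deg, y_deg, geometry: ScreenGeometry):
    """Inverse of :func:`px_to_deg` (exact up to float rounding)."""
    cx, cy = geometry.center_px
    x_px = np.asarray(x_deg, dtype=float) / geometry.deg_per_px_x + cx
    y_px = cy - np.asarray(y_deg, dtype=float) / geometry.deg_per_px_y
    return x_px, y_px
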