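"""AOI construction, response scoring and trial-level filtering.

A response is correct when, at the sample nearest the button press, the left
eye, the right eye, or the binocular average lies inside the padded target
AOI. Only correct trials enter the downstream reaction-time and eye-movement
analyses; timeouts count as errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .geometry import ScreenGeometry
from .types import AOIRect, GazeTrace, TrialRecord

__all__ = ["make_aoi", "score_response", "build_analysis_set", "TrialAccounting"]


def make_aoi(target_box: AOIRect, padding_deg: float,
             geometry: ScreenGeometry) -> AOIRect:
    """Expand a tight target box by `padding_deg` on every side.

    Padding converts to pixels per axis (the horizontal and vertical px/deg
    factors differ slightly); the result is clipped to the screen.
    """
    if padding_deg < 0:
        raise ValueError("padding must be non-negative")
    px = padding_deg / geometry.deg_per_px_x
    py = padding_deg / geometry.deg_per_px_y
    return AOIRect(
        max(0.0, target_box.x0 - px),
        max(0.0, target_box.y0 - py),
        min(float(geometry.width_px), target_box.x1 + px),
        min(float(geometry.height_px), target_box.y1 + py),
    )


def score_response(trial: TrialRecord, trace: Optional[GazeTrace],
                   window_ms: int = 0) -> bool:
    """Score one trial; timeouts are incorrect without any sample lookup.

    ``window_ms`` widens the lookup from the single nearest sample to any
    sample within +-window of the press (default: the press sample only).
    """
    if trial.timed_out:
        return False
    if trace is None or len(trace) == 0:
        raise ValueError(f"trial {trial.key}: no samples to score")
    rt = trial.response_time_ms
    idx = int(np.argmin(np.abs(trace.t - rt)))
    if abs(int(trace.t[idx]) - rt) > max(window_ms, 20):
        raise ValueError(f"trial {trial.key}: no sample near the button press")
    lo = max(0, idx - window_ms)
    hi = min(len(trace), idx + window_ms + 1)
    aoi = trial.aoi
    for i in range(lo, hi):
        if trace.valid_left[i] and aoi.contains(trace.x_left[i], trace.y_left[i]):
            return True
        if trace.valid_right[i] and aoi.contains(trace.x_right[i], trace.y_right[i]):
            return True
        if trace.valid_left[i] and trace.valid_right[i]:
            ax = 0.5 * (trace.x_left[i] + trace.x_right[i])
            ay = 0.5 * (trace.y_left[i] + trace.y_right[i])
            if aoi.contains(ax, ay):
                return True
    return False


@dataclass(frozen=True)
class TrialAccounting:
    """Bookkeeping of the analysis set."""

    recorded: int
    timed_out: int
    responded: int
    correct: int

    @property
    def correct_rate(self) -> Optional[float]:
        """Correct / recorded; None for an empty session."""
        return self.correct / self.recorded if self.recorded else None

    @property
    def correct_rate_responded(self) -> Optional[float]:
        """Correct / responded (timeouts dropped from the denominator)."""
        return self.correct / self.responded if self.responded else None

    @property
    def timeout_rate(self) -> Optional[float]:
        return self.timed_out / self.recorded if self.recorded else None


def build_analysis_set(trials: Iterable[TrialRecord]
                       ) -> tuple[list[TrialRecord], TrialAccounting]:
    """Keep correct trials; return them with the full accounting.

    Every trial must already carry a ``correct`` flag (timeouts are scored
    incorrect).
    """
    trials = list(trials)
    for tr in trials:
        if tr.correct is None:
            raise ValueError(f"trial {tr.key} has not been scored")
    recorded = len(trials)
    timed_out = sum(tr.timed_out for tr in trials)
    correct_trials = [tr for tr in trials if tr.correct]
    acct = TrialAccounting(
        recorded=recorded,
        timed_out=timed_out,
        responded=recorded - timed_out,
        correct=len(correct_trials),
    )
    return correct_trials, acct
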