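"""Search-efficiency metrics: scan-path ratio and search time.

The scan-path ratio (SPR) divides the path the eyes actually travelled —
the summed amplitudes of all saccades completed up to and including the one
landing in the first target fixation — by the most efficient possible path,
the straight line from the screen centre to the target centre in degree
space. SPR = 1 is a direct, maximally efficient path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .geometry import ScreenGeometry, px_to_deg
from .types import EventSequence, FixationEvent, TrialRecord

__all__ = ["EfficiencyMetrics", "scan_path_ratio", "search_time"]


@dataclass(frozen=True)
class EfficiencyMetrics:
    scan_path_ratio: float
    path_length: float       # degrees
    optimal_path: float      # degrees
    search_time_ms: Optional[int]
    n_saccades_to_target: int


def scan_path_ratio(events: EventSequence, trial: TrialRecord,
                    geometry: ScreenGeometry) -> Optional[EfficiencyMetrics]:
    """Efficiency metrics of one correct trial, or None when undefined.

    The metric is undefined (and the trial excluded, to be counted by the
    caller) when no fixation centroid ever falls inside the target AOI.
    """
    target_fix: Optional[FixationEvent] = None
    for f in events.fixations:
        if f.ordinal >= 1 and trial.aoi.contains(f.x, f.y):
            target_fix = f
            break
    if target_fix is None:
        return None
    saccades = [s for s in events.saccades
                if s.t_start >= 0 and s.t_end <= target_fix.t_start]
    path = sum(s.amplitude for s in saccades)
    tx, ty = px_to_deg(*trial.target_center, geometry)
    optimal = math.hypot(float(tx), float(ty))
    if optimal <= 0:
        raise ValueError("target at screen centre: optimal path undefined")
    return EfficiencyMetrics(
        scan_path_ratio=path / optimal, path_length=path,
        optimal_path=optimal, search_time_ms=trial.response_time_ms,
        n_saccades_to_target=len(saccades))


def search_time(trial: TrialRecord) -> Optional[int]:
    """Scene onset -> button press, in ms; None for timed-out trials."""
    return None if trial.timed_out else trial.response_time_ms
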