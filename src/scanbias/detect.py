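"""Velocity/acceleration-threshold parsing of raw gaze into events.

The detector classifies each 1 kHz sample as fixation, saccade or blink:

1. runs of invalid samples become blinks, padded by ``blink_pad_ms`` on each
   side (tracker positions are unreliable while the lid moves);
2. within each valid segment, positions are smoothed with a centred moving
   average and differentiated with a centred 5-point difference; a run of
   samples with speed above ``velocity_threshold`` is a saccade if its peak
   acceleration exceeds ``acceleration_threshold`` and the chord displacement
   exceeds ``motion_threshold`` — onsets are reported at the velocity
   crossing, which keeps onset latency small for small saccades;
3. complementary intervals are fixations; fixation fragments shorter than
   ``min_fixation_ms`` merge into their neighbouring saccades.

Thresholds default to the widely used "cognitive" parser settings
(30 deg/s, 8000 deg/s^2, 0.1 deg). Events overlapping or touching a blink
are flagged ``blink_adjacent``; fixations with centroids outside the screen
are flagged ``offscreen``. Fixation #0 is the fixation containing scene
onset (t = 0); saccade ordinal 1 is the first saccade after onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import ScreenGeometry, px_to_deg
from .types import (BlinkEvent, EventSequence, FixationEvent, GazeTrace,
                    SaccadeEvent, TrialRecord)

__all__ = ["DetectorParams", "detect_events", "apply_exclusions"]


@dataclass(frozen=True)
class DetectorParams:
    velocity_threshold: float = 30.0      # deg/s
    acceleration_threshold: float = 8000.0  # deg/s^2
    motion_threshold: float = 0.1         # deg
    min_fixation_ms: int = 40
    smoothing_window_samples: int = 5
    blink_pad_ms: int = 50

    def __post_init__(self) -> None:
        if min(self.velocity_threshold, self.acceleration_threshold,
               self.motion_threshold) <= 0:
            raise ValueError("detector thresholds must be positive")
        w = self.smoothing_window_samples
        if w < 3 or w % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 3")


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if len(x) == 0:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _segment_events(xd: np.ndarray, yd: np.ndarray, t0: int,
                    params: DetectorParams) -> list[tuple[str, int, int]]:
    """(kind, start, end) half-open intervals covering one valid segment."""
    n = len(xd)
    xs = _smooth(xd, params.smoothing_window_samples)
    ys = _smooth(yd, params.smoothing_window_samples)
    # centred 5-point difference -> deg/ms; thresholds are per second
    vx = np.zeros(n)
    vy = np.zeros(n)
    if n > 4:
        vx[2:-2] = (xs[4:] - xs[:-4]) / 4.0
        vy[2:-2] = (ys[4:] - ys[:-4]) / 4.0
    speed = np.hypot(vx, vy) * 1000.0
    accel = np.zeros(n)
    if n > 2:
        accel[1:-1] = (speed[2:] - speed[:-2]) / 2.0 * 1000.0

    fast = speed >= params.velocity_threshold  # at-threshold ties are saccadic
    events: list[tuple[str, int, int]] = []
    i = 0
    prev_end = 0
    while i < n:
        if not fast[i]:
            i += 1
            continue
        j = i
        while j < n and fast[j]:
            j += 1
        # confirm the burst as a saccade
        a_peak = np.max(np.abs(accel[i:j])) if j > i else 0.0
        p0 = max(i - 1, 0)
        p1 = min(j, n - 1)
        disp = float(np.hypot(xd[p1] - xd[p0], yd[p1] - yd[p0]))
        if a_peak >= params.acceleration_threshold and disp > params.motion_threshold:
            if i > prev_end:
                events.append(("fix", prev_end, i))
            events.append(("sacc", i, j))
            prev_end = j
        i = j
    if prev_end < n:
        events.append(("fix", prev_end, n))

    # fixation fragments shorter than min_fixation_ms merge into neighbours
    merged: list[tuple[str, int, int]] = []
    for kind, a, b in events:
        if kind == "fix" and b - a < params.min_fixation_ms:
            if merged and merged[-1][0] == "sacc":
                merged[-1] = ("sacc", merged[-1][1], b)
            else:
                merged.append((kind, a, b))  # leading fragment: next saccade absorbs it
            continue
        if kind == "sacc" and merged and merged[-1][2] == a and (
                merged[-1][0] == "sacc"
                or merged[-1][2] - merged[-1][1] < params.min_fixation_ms):
            merged[-1] = ("sacc", merged[-1][1], b)
        else:
            merged.append((kind, a, b))
    return [(k, a + t0, b + t0) for k, a, b in merged]


def detect_events(trace: GazeTrace, params: DetectorParams,
                  geometry: ScreenGeometry, eye: str = "right"
                  ) -> EventSequence:
    """Parse one trial's raw trace into fixations, saccades and blinks."""
    if len(trace) < params.smoothing_window_samples:
        raise ValueError("trial shorter than the smoothing window")
    x_px, y_px, valid = trace.eye_positions(eye)
    t = trace.t
    n = len(trace)

    # --- blink intervals: padded runs of invalid samples --------------
    blink_mask = np.zeros(n, dtype=bool)
    inv = ~np.asarray(valid, dtype=bool)
    if inv.any():
        idx = np.flatnonzero(np.diff(np.concatenate(([0], inv.view(np.int8), [0]))))
        pad = params.blink_pad_ms
        for a, b in zip(idx[::2], idx[1::2]):
            blink_mask[max(0, a - pad):min(n, b + pad)] = True

    xd, yd = px_to_deg(x_px, y_px, geometry)

    events: list = []
    cursor = 0
    while cursor < n:
        if blink_mask[cursor]:
            end = cursor
            while end < n and blink_mask[end]:
                end += 1
            events.append(BlinkEvent(int(t[cursor]), int(t[end - 1]) + 1))
            cursor = end
            continue
        end = cursor
        while end < n and not blink_mask[end]:
            end += 1
        for kind, a, b in _segment_events(xd[cursor:end], yd[cursor:end],
                                          cursor, params):
            if kind == "fix":
                cx = float(np.mean(x_px[a:b]))
                cy = float(np.mean(y_px[a:b]))
                off = not (0 <= cx < geometry.width_px
                           and 0 <= cy < geometry.height_px)
                events.append(FixationEvent(
                    ordinal=0, t_start=int(t[a]), t_end=int(t[b - 1]) + 1,
                    x=cx, y=cy, offscreen=off))
            else:
                p0, p1 = max(a - 1, cursor), min(b, end - 1)
                dx = float(xd[p1] - xd[p0])
                dy = float(yd[p1] - yd[p0])
                amp = float(np.hypot(dx, dy))
                direction = float(np.degrees(np.arctan2(dy, dx)) % 360.0)
                events.append(SaccadeEvent(
                    ordinal=0, t_start=int(t[a]), t_end=int(t[b - 1]) + 1,
                    x_start=float(x_px[p0]), y_start=float(y_px[p0]),
                    x_end=float(x_px[p1]), y_end=float(y_px[p1]),
                    amplitude=amp, direction=direction))
        cursor = end

    events.sort(key=lambda e: e.t_start)

    # --- blink adjacency ----------------------------------------------
    blink_spans = [(e.t_start, e.t_end) for e in events
                   if isinstance(e, BlinkEvent)]
    for ev in events:
        if isinstance(ev, BlinkEvent):
            continue
        for b0, b1 in blink_spans:
            if ev.t_start <= b1 and ev.t_end >= b0:
                ev.blink_adjacent = True
                break

    # --- ordinals -------------------------------------------------------
    fixes = [e for e in events if isinstance(e, FixationEvent)]
    anchor = 0
    for k, f in enumerate(fixes):
        if f.t_start <= 0 < f.t_end:
            anchor = k
            break
    else:
        post = [k for k, f in enumerate(fixes) if f.t_start >= 0]
        anchor = post[0] if post else 0
    for k, f in enumerate(fixes):
        f.ordinal = k - anchor
    saccs = [e for e in events if isinstance(e, SaccadeEvent)]
    post = [k for k, s in enumerate(saccs) if s.t_start >= 0]
    s_anchor = post[0] if post else 0
    for k, s in enumerate(saccs):
        s.ordinal = k - s_anchor + 1

    return EventSequence(events)


_STAGES = ("generic", "duration_means", "duration_timecourse")


def apply_exclusions(events: EventSequence, trial: Optional[TrialRecord],
                     stage: str = "generic") -> EventSequence:
    """Filter a trial's events for a given analysis stage.

    ``generic`` removes off-screen fixations and blink-contaminated
    fixations/saccades. ``duration_means`` additionally removes fixation #0,
    the trial's last fixation, and the fixation during which the button
    press fell. ``duration_timecourse`` keeps fixation #0 — with its
    duration re-based to scene onset — while applying the other removals.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown exclusion stage {stage!r}; "
                         f"expected one of {_STAGES}")
    fixes = events.fixations
    drop = set()
    if stage in ("duration_means", "duration_timecourse"):
        if fixes:
            drop.add(id(fixes[-1]))  # last fixation in the trial
        if trial is not None and trial.response_time_ms is not None:
            rt = trial.response_time_ms
            for f in fixes:
                if f.t_start <= rt < f.t_end:
                    drop.add(id(f))
        if stage == "duration_means":
            for f in fixes:
                if f.ordinal == 0:
                    drop.add(id(f))

    out = []
    for ev in events:
        if isinstance(ev, BlinkEvent):
            continue
        if ev.blink_adjacent:
            continue
        if isinstance(ev, FixationEvent):
            if ev.offscreen or id(ev) in drop:
                continue
            if stage == "duration_timecourse" and ev.ordinal == 0:
                # analytic duration of fixation #0: scene onset -> saccade 1
                ev = replace(ev, t_start=max(ev.t_start, 0))
        out.append(ev)
    return EventSequence(out)
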