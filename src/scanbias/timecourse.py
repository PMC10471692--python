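"""Millisecond-resolution pseudoneglect curves and ordinal-position analyses.

The central quantity is the horizontal deviation of average binocular gaze
from the vertical scene midline, in degrees, negative to the left. Per
millisecond, trial curves (defined from scene onset until the button press)
are averaged within subject over the trials still ongoing, subject curves
are averaged across subjects, and uncertainty comes from a percentile
bootstrap that resamples *subjects* with replacement. The curve is reported
up to the last millisecond at which at least half of the subjects still
contribute.

Ordinal-position analyses summarise fixation durations, saccade amplitudes
and leftward-saccade proportions by their ordinal position in the scan
path, with Cousineau–Morey within-subject standard errors across the two
target-side conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .bias import dichotomize_direction
from .detect import apply_exclusions
from .geometry import ScreenGeometry
from .types import EventSequence, FixationEvent, GazeTrace, SaccadeEvent, TrialRecord

__all__ = [
    "TimeCourseCurve",
    "horizontal_deviation_curve",
    "ordinal_curves",
    "cousineau_morey_se",
]


@dataclass
class TimeCourseCurve:
    """Mean horizontal gaze deviation per millisecond with bootstrap CI."""

    t: np.ndarray
    mean_dev: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_subjects_at_t: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t, "mean_dev_deg": self.mean_dev,
            "ci_low_deg": self.ci_low, "ci_high_deg": self.ci_high,
            "n_subjects": self.n_subjects_at_t,
        })


def _subject_curves(trials: Sequence[tuple[TrialRecord, GazeTrace]],
                    geometry: ScreenGeometry) -> tuple[list[str], np.ndarray]:
    """Per-subject mean-deviation curves (subjects x ms matrix, NaN padded)."""
    cx = geometry.center_px[0]
    kx = geometry.deg_per_px_x
    per_subject: dict[str, list[np.ndarray]] = {}
    t_max = 0
    for trial, trace in trials:
        if trial.response_time_ms is None:
            continue
        rt = trial.response_time_ms
        sel = (trace.t >= 0) & (trace.t < rt)
        dev = (trace.binocular_x()[sel] - cx) * kx
        per_subject.setdefault(trial.subject_id, []).append(dev)
        t_max = max(t_max, len(dev))
    if not per_subject or t_max == 0:
        raise ValueError("no ongoing trials at t = 0")
    subjects = sorted(per_subject)
    curves = np.full((len(subjects), t_max), np.nan)
    for i, sid in enumerate(subjects):
        devs = per_subject[sid]
        acc = np.zeros(t_max)
        cnt = np.zeros(t_max)
        for dev in devs:
            ok = ~np.isnan(dev)
            acc[:len(dev)][ok] += dev[ok]
            cnt[:len(dev)][ok] += 1
        with np.errstate(invalid="ignore"):
            curves[i] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return subjects, curves


def horizontal_deviation_curve(
        trials: Sequence[tuple[TrialRecord, GazeTrace]],
        geometry: ScreenGeometry,
        condition: Optional[str] = None,
        bootstrap_B: int = 2000,
        rng: Optional[np.random.Generator] = None,
        ci_level: float = 0.95,
        horizon_frac: float = 0.5) -> TimeCourseCurve:
    """Grand-average horizontal-deviation curve with a bootstrap CI.

    ``trials`` should contain correct trials only (timed-out trials are
    skipped). ``condition`` restricts to one target side ('left'/'right').
    """
    if condition is not None:
        trials = [(tr, g) for tr, g in trials if tr.target_side == condition]
    subjects, curves = _subject_curves(trials, geometry)
    S = len(subjects)
    contrib = ~np.isnan(curves)
    n_at_t = contrib.sum(axis=0)

    horizon_n = math.ceil(horizon_frac * S)
    ok = np.flatnonzero(n_at_t >= horizon_n)
    t_last = int(ok.max()) + 1 if ok.size else 1
    curves = curves[:, :t_last]
    contrib = contrib[:, :t_last]
    n_at_t = n_at_t[:t_last]

    with np.errstate(invalid="ignore"):
        grand = np.nansum(curves, axis=0) / np.maximum(n_at_t, 1)
    grand[n_at_t == 0] = np.nan

    rng = rng or np.random.default_rng()
    filled = np.nan_to_num(curves)
    valid = contrib.astype(float)
    draws = rng.integers(0, S, size=(int(bootstrap_B), S))
    weights = np.zeros((int(bootstrap_B), S))
    for b in range(int(bootstrap_B)):
        weights[b] = np.bincount(draws[b], minlength=S)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = (weights @ filled) / (weights @ valid)
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    ci_low = np.nanpercentile(boot, alpha, axis=0)
    ci_high = np.nanpercentile(boot, 100.0 - alpha, axis=0)

    return TimeCourseCurve(
        t=np.arange(t_last), mean_dev=grand,
        ci_low=ci_low, ci_high=ci_high, n_subjects_at_t=n_at_t)


def cousineau_morey_se(matrix) -> np.ndarray:
    """Within-subject SEs for an n_subjects x M repeated-measures matrix.

    Scores are centred on each subject's mean and shifted back by the grand
    mean; per-condition SEs of the normalised scores carry the
    sqrt(M / (M - 1)) bias correction.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a complete n_subjects x M matrix with n, M >= 2")
    if np.isnan(y).any():
        raise ValueError("matrix has missing cells; drop incomplete subjects first")
    n, m = y.shape
    normalized = y - y.mean(axis=1, keepdims=True) + y.mean()
    se = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    return se * np.sqrt(m / (m - 1))


_MEASURES = ("fixation_duration", "saccade_amplitude", "leftward_proportion")


def _event_values(seq: EventSequence, measure: str) -> list[tuple[int, float]]:
    out = []
    if measure == "fixation_duration":
        for f in seq.fixations:
            if f.ordinal >= 0:
                out.append((f.ordinal, float(f.duration)))
    else:
        for s in seq.saccades:
            if s.ordinal < 1:
                continue
            if measure == "saccade_amplitude":
                out.append((s.ordinal, s.amplitude))
            else:
                d = dichotomize_direction(s.direction)
                if d != "undefined":
                    out.append((s.ordinal, 1.0 if d == "left" else 0.0))
    return out


def ordinal_curves(trial_events: Iterable[tuple[TrialRecord, EventSequence]],
                   measure: str,
                   min_subjects: int = 3) -> pd.DataFrame:
    """Ordinal-position curves of an oculomotor measure, by target side.

    Returns a tidy frame with columns ``ordinal, condition, mean,
    within_subject_se, n_subjects, n_observations``; conditions are 'left',
    'right' and 'pooled'. Ordinals are truncated once either target-side
    condition has fewer than ``min_subjects`` contributing subjects. The SE
    is the Cousineau–Morey within-subject SE across the two side conditions
    (subjects contributing to both sides at that ordinal); the pooled
    condition carries the classical between-subject SE.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {_MEASURES}")
    stage = "duration_timecourse" if measure == "fixation_duration" else "generic"

    # per (subject, side, ordinal) running sums of the measure
    acc: dict[tuple[str, str, int], list[float]] = {}
    for trial, seq in trial_events:
        filtered = apply_exclusions(seq, trial, stage)
        for ordinal, value in _event_values(filtered, measure):
            acc.setdefault((trial.subject_id, trial.target_side, ordinal),
                           []).append(value)

    frame = pd.DataFrame(
        [(s, side, o, float(np.mean(v)), len(v))
         for (s, side, o), v in acc.items()],
        columns=["subject", "side", "ordinal", "mean", "n_obs"])
    if frame.empty:
        return pd.DataFrame(columns=["ordinal", "condition", "mean",
                                     "within_subject_se", "n_subjects",
                                     "n_observations"])

    rows = []
    for o in sorted(frame["ordinal"].unique()):
        g = frame[frame["ordinal"] == o]
        wide = g.pivot_table(index="subject", columns="side", values="mean")
        sides_present = [c for c in ("left", "right") if c in wide.columns]
        n_by_side = {c: int(wide[c].notna().sum()) for c in sides_present}
        if (len(sides_present) < 2
                or min(n_by_side.values()) < min_subjects):
            break
        complete = wide.dropna()
        se = (cousineau_morey_se(complete[["left", "right"]].to_numpy())
              if len(complete) >= 2 else np.array([np.nan, np.nan]))
        for j, side in enumerate(("left", "right")):
            sub = g[g["side"] == side]
            rows.append({
                "ordinal": int(o), "condition": side,
                "mean": float(sub["mean"].mean()),
                "within_subject_se": float(se[j]),
                "n_subjects": n_by_side[side],
                "n_observations": int(sub["n_obs"].sum())})
        pooled = g.groupby("subject")["mean"].mean()
        rows.append({
            "ordinal": int(o), "condition": "pooled",
            "mean": float(pooled.mean()),
            "within_subject_se": float(pooled.std(ddof=1) / np.sqrt(len(pooled)))
            if len(pooled) > 1 else np.nan,
            "n_subjects": int(len(pooled)),
            "n_observations": int(g["n_obs"].sum())})
    return pd.DataFrame(rows)
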