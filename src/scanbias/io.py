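"""Readers and writers for the tabular report formats.

Three plain-text formats move data between pipeline stages:

* **sample report** (TSV) — per-millisecond binocular gaze positions,
  columns ``subject_id, scene_id, t_ms, x_left_px, y_left_px, x_right_px,
  y_right_px, valid_left, valid_right``;
* **fixation report** (TSV) — one row per parsed event, columns
  ``subject_id, scene_id, event_type, ordinal, t_start_ms, t_end_ms, x_px,
  y_px, x_end_px, y_end_px, amplitude_deg, direction_deg, duration_ms,
  blink_adjacent, offscreen``;
* **trial metadata** (CSV) — design cell, AOI rectangle and response per
  trial.

All dialects are UTF-8 with '.' decimals; missing values are the sentinel
``"."`` (mirroring common tracker-export conventions).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (AOIRect, BlinkEvent, EventSequence, FixationEvent,
                    GazeTrace, SaccadeEvent, TrialRecord)

__all__ = [
    "FormatError",
    "DataError",
    "SAMPLE_COLUMNS",
    "FIXATION_COLUMNS",
    "TRIAL_COLUMNS",
    "read_sample_report",
    "write_sample_report",
    "read_fixation_report",
    "write_fixation_report",
    "read_trial_metadata",
    "write_trial_metadata",
]

SENTINEL = "."

SAMPLE_COLUMNS = [
    "subject_id", "scene_id", "t_ms",
    "x_left_px", "y_left_px", "x_right_px", "y_right_px",
    "valid_left", "valid_right",
]

FIXATION_COLUMNS = [
    "subject_id", "scene_id", "event_type", "ordinal",
    "t_start_ms", "t_end_ms", "x_px", "y_px", "x_end_px", "y_end_px",
    "amplitude_deg", "direction_deg", "duration_ms",
    "blink_adjacent", "offscreen",
]

TRIAL_COLUMNS = [
    "subject_id", "scene_id", "target_side", "orientation",
    "aoi_x0", "aoi_y0", "aoi_x1", "aoi_y1",
    "target_cx", "target_cy", "response_time_ms", "timed_out",
]


class FormatError(ValueError):
    """The file does not match the documented report format."""


class DataError(ValueError):
    """The file parses but its content violates a data invariant."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing mandatory column(s): "
                          + ", ".join(missing))


# ---------------------------------------------------------------- samples

def _numeric(col: pd.Series) -> np.ndarray:
    """Parse a numeric column; malformed cells (incl. the sentinel) -> NaN."""
    return pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)


def read_sample_report(path, rebase: bool = True) -> Iterator[tuple[tuple[str, str], GazeTrace]]:
    """Yield ``((subject_id, scene_id), GazeTrace)`` per trial, in file order.

    Malformed numeric position cells make the affected eye invalid for that
    sample. When ``rebase`` is true, trial time is shifted so the first
    non-negative sample sits at t = 0 (t stays untouched for trials already
    based at scene onset).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(df, SAMPLE_COLUMNS, "sample report")
    for key, g in df.groupby(["subject_id", "scene_id"], sort=False):
        t = pd.to_numeric(g["t_ms"], errors="coerce")
        if t.isna().any():
            raise DataError(f"trial {key}: non-numeric t_ms")
        t = t.to_numpy(dtype=np.int64)
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            raise DataError(f"trial {key}: t_ms not strictly increasing at 1 ms steps")
        xl, yl = _numeric(g["x_left_px"]), _numeric(g["y_left_px"])
        xr, yr = _numeric(g["x_right_px"]), _numeric(g["y_right_px"])
        vl = g["valid_left"].astype(str).str.strip().isin(["1", "True", "true"])
        vr = g["valid_right"].astype(str).str.strip().isin(["1", "True", "true"])
        vl = vl.to_numpy() & ~np.isnan(xl) & ~np.isnan(yl)
        vr = vr.to_numpy() & ~np.isnan(xr) & ~np.isnan(yr)
        xl[~vl] = np.nan
        yl[~vl] = np.nan
        xr[~vr] = np.nan
        yr[~vr] = np.nan
        if rebase and t[0] > 0:
            t = t - t[0]
        yield (str(key[0]), str(key[1])), GazeTrace(t, xl, yl, xr, yr, vl, vr)


def write_sample_report(trials: Iterable[tuple[tuple[str, str], GazeTrace]],
                        path) -> None:
    """Write trials to a sample-report TSV (lossless round-trip)."""
    frames = []
    for (subject_id, scene_id), trace in trials:
        frames.append(pd.DataFrame({
            "subject_id": subject_id,
            "scene_id": scene_id,
            "t_ms": trace.t,
            "x_left_px": trace.x_left,
            "y_left_px": trace.y_left,
            "x_right_px": trace.x_right,
            "y_right_px": trace.y_right,
            "valid_left": trace.valid_left.astype(int),
            "valid_right": trace.valid_right.astype(int),
        }))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=SAMPLE_COLUMNS))
    out.to_csv(path, sep="\t", index=False, na_rep=SENTINEL,
               float_format="%.6f")


# ---------------------------------------------------------------- events

def _event_row(subject_id: str, scene_id: str, ev) -> dict:
    row = dict.fromkeys(FIXATION_COLUMNS, np.nan)
    row.update(subject_id=subject_id, scene_id=scene_id,
               t_start_ms=ev.t_start, t_end_ms=ev.t_end,
               duration_ms=ev.duration)
    if isinstance(ev, FixationEvent):
        row.update(event_type="FIX", ordinal=ev.ordinal, x_px=ev.x, y_px=ev.y,
                   blink_adjacent=int(ev.blink_adjacent),
                   offscreen=int(ev.offscreen))
    elif isinstance(ev, SaccadeEvent):
        row.update(event_type="SACC", ordinal=ev.ordinal,
                   x_px=ev.x_start, y_px=ev.y_start,
                   x_end_px=ev.x_end, y_end_px=ev.y_end,
                   amplitude_deg=ev.amplitude, direction_deg=ev.direction,
                   blink_adjacent=int(ev.blink_adjacent), offscreen=0)
    elif isinstance(ev, BlinkEvent):
        row.update(event_type="BLINK", blink_adjacent=0, offscreen=0)
    else:  # pragma: no cover - guarded by the type union
        raise TypeError(f"unknown event type {type(ev)!r}")
    return row


def write_fixation_report(sequences: Mapping[tuple[str, str], EventSequence],
                          path) -> None:
    """Write parsed event sequences to a fixation-report TSV."""
    rows = [_event_row(sid, scid, ev)
            for (sid, scid), seq in sequences.items() for ev in seq]
    df = pd.DataFrame(rows, columns=FIXATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep=SENTINEL,
              float_format="%.6f")


def read_fixation_report(path) -> dict[tuple[str, str], EventSequence]:
    """Read a fixation-report TSV back into per-trial event sequences."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(df, FIXATION_COLUMNS, "fixation report")
    out: dict[tuple[str, str], EventSequence] = {}
    for key, g in df.groupby(["subject_id", "scene_id"], sort=False):
        events = []
        for _, r in g.iterrows():
            t0, t1 = int(float(r["t_start_ms"])), int(float(r["t_end_ms"]))
            kind = r["event_type"]
            if kind == "FIX":
                events.append(FixationEvent(
                    ordinal=int(float(r["ordinal"])), t_start=t0, t_end=t1,
                    x=float(r["x_px"]), y=float(r["y_px"]),
                    blink_adjacent=bool(int(float(r["blink_adjacent"]))),
                    offscreen=bool(int(float(r["offscreen"])))))
            elif kind == "SACC":
                events.append(SaccadeEvent(
                    ordinal=int(float(r["ordinal"])), t_start=t0, t_end=t1,
                    x_start=float(r["x_px"]), y_start=float(r["y_px"]),
                    x_end=float(r["x_end_px"]), y_end=float(r["y_end_px"]),
                    amplitude=float(r["amplitude_deg"]),
                    direction=float(r["direction_deg"]),
                    blink_adjacent=bool(int(float(r["blink_adjacent"])))))
            elif kind == "BLINK":
                events.append(BlinkEvent(t_start=t0, t_end=t1))
            else:
                raise FormatError(f"unknown event_type {kind!r}")
        out[(str(key[0]), str(key[1]))] = EventSequence(events)
    return out


# ---------------------------------------------------------------- trials

def write_trial_metadata(trials: Iterable[TrialRecord], path) -> None:
    """Write trial metadata; a `correct` column is added once trials are scored."""
    trials = list(trials)
    scored = any(tr.correct is not None for tr in trials)
    rows = []
    for tr in trials:
        row = {
            "subject_id": tr.subject_id, "scene_id": tr.scene_id,
            "target_side": tr.target_side, "orientation": tr.orientation,
            "aoi_x0": tr.aoi.x0, "aoi_y0": tr.aoi.y0,
            "aoi_x1": tr.aoi.x1, "aoi_y1": tr.aoi.y1,
            "target_cx": tr.target_center[0], "target_cy": tr.target_center[1],
            "response_time_ms": (np.nan if tr.response_time_ms is None
                                 else tr.response_time_ms),
            "timed_out": int(tr.timed_out),
        }
        if scored:
            row["correct"] = (np.nan if tr.correct is None
                              else int(tr.correct))
        rows.append(row)
    cols = TRIAL_COLUMNS + (["correct"] if scored else [])
    pd.DataFrame(rows, columns=cols).to_csv(
        path, index=False, na_rep=SENTINEL, float_format="%.6f")


def read_trial_metadata(path) -> list[TrialRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, TRIAL_COLUMNS, "trial metadata")
    trials = []
    for _, r in df.iterrows():
        rt = r["response_time_ms"]
        timed_out = bool(int(float(r["timed_out"])))
        correct = None
        if "correct" in df.columns and r["correct"] != SENTINEL:
            correct = bool(int(float(r["correct"])))
        trials.append(TrialRecord(
            subject_id=str(r["subject_id"]), scene_id=str(r["scene_id"]),
            target_side=r["target_side"], orientation=r["orientation"],
            aoi=AOIRect(float(r["aoi_x0"]), float(r["aoi_y0"]),
                        float(r["aoi_x1"]), float(r["aoi_y1"])),
            target_center=(float(r["target_cx"]), float(r["target_cy"])),
            response_time_ms=None if (timed_out or rt == SENTINEL)
            else int(float(rt)),
            timed_out=timed_out,
            correct=correct,
        ))
    return trials
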