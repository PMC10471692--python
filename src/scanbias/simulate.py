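"""Synthetic scan-path generator.

Generates complete synthetic search experiments — counterbalanced trial
designs, target AOI geometry, and 1 kHz binocular raw-gaze traces — carrying
the oculomotor regularities the analyses assume:

* a left-biased first saccade whose bias is weaker for right-side targets
  (marginal leftward probabilities are *exactly* ``p_left_L`` / ``p_left_R``
  by construction: the hemifield is drawn first, then a direction within it);
* horizontal and downward direction biases for non-guided saccades;
* fixation durations rising to an asymptote over ordinal position and
  saccade amplitudes that rise, plateau, then fall;
* target guidance that escalates over the scan path, AOI-contingent button
  presses after a motor delay, occasional false presses on distractors,
  blinks, and a 15 s timeout.

Every trial returns its ground-truth event sequence alongside the raw trace,
so the event detector can be validated sample-exactly. Saccade kinematics use
a raised-cosine position profile with a classic linear main sequence
(duration = 21 + 2.2 x amplitude ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from scipy import stats as sps

from .geometry import ScreenGeometry, deg_to_px, px_to_deg
from .scoring import make_aoi
from .types import (AOIRect, BlinkEvent, EventSequence, FixationEvent,
                    GazeTrace, SaccadeEvent, TrialRecord)

__all__ = [
    "SimulatorConfig",
    "SceneDesign",
    "SimulatedTrial",
    "build_design",
    "validate_design",
    "simulate_trial",
    "simulate_experiment",
    "mirror_trial",
]

DEFAULT_AMP_SCHEDULE = (4.0, 5.3, 5.3, 5.0, 4.6, 4.2, 4.0, 3.8, 3.6, 3.5, 3.4, 3.3)


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions of the emulated experiment.

    Defaults describe the emulated study: 22 subjects x 148 scenes on an
    800x600 px / 25.78x19.34 deg display, leftward first-saccade
    probabilities 0.774 (L-targets) and 0.670 (R-targets) — the inverse
    logits of the condition estimates the analyses are meant to recover —
    a 0.6 downward direction mass, escalating target guidance, and a 15 s
    response timeout.
    """

    n_subjects: int = 22
    n_scenes: int = 148
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    # first-saccade direction bias (marginal hemifield probabilities)
    p_left_L: float = 0.774
    p_left_R: float = 0.670
    p_down: float = 0.6
    # guidance: probability a saccade is target-directed
    first_guidance: float = 0.35
    guidance_gain: float = 0.55
    guidance_step: float = 0.1
    guidance_max: float = 0.95
    # saccade amplitudes (deg) by ordinal and their spread
    amp_schedule: tuple = DEFAULT_AMP_SCHEDULE
    amp_cv: float = 0.3
    min_amplitude_deg: float = 1.2
    landing_sd_deg: float = 1.0
    direction_noise_kappa: float = 4.0
    base_direction_kappa: float = 1.5
    # fixation durations (ms)
    fix0_mean_ms: float = 250.0
    fix0_shape: float = 8.0
    fixdur_start_ms: float = 185.0
    fixdur_asymptote_ms: float = 265.0
    fixdur_rate: float = 0.6
    fixdur_cv: float = 0.25
    # response generation
    p_recognize_on_target_fix: float = 0.85
    p_false_press: float = 0.06
    motor_delay_ms: int = 500
    timeout_ms: int = 15000
    # noise processes
    blink_rate_per_trial: float = 0.3
    blink_pad_ms: int = 50
    binocular_jitter_sd_deg: float = 0.05
    # optional per-scene heterogeneity of the left bias (logit scale)
    item_logit_sd: float = 0.0
    # scene/AOI geometry (deg)
    aoi_width_deg: float = 3.17
    aoi_height_deg: float = 3.29
    aoi_padding_deg: float = 0.75
    target_ecc_x_range: tuple = (3.5, 9.5)
    target_y_range: tuple = (-6.5, 4.5)
    pre_onset_ms: int = 600

    def __post_init__(self) -> None:
        for name in ("p_left_L", "p_left_R", "p_down", "first_guidance",
                     "guidance_gain", "guidance_max",
                     "p_recognize_on_target_fix", "p_false_press"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.amp_schedule:
            raise ValueError("amp_schedule must be non-empty")
        if self.timeout_ms <= 0:
            raise ValueError("timeout_ms must be positive")

    def p_left(self, target_side: str) -> float:
        return self.p_left_L if target_side == "left" else self.p_left_R


@dataclass(frozen=True)
class SceneDesign:
    """One base scene: target placement in degrees, in *normal* orientation."""

    scene_id: str
    base_side: str  # side of the target in the normal orientation
    target_center_deg: tuple[float, float]

    def center_for(self, orientation: str) -> tuple[float, float]:
        x, y = self.target_center_deg
        return (x, y) if orientation == "normal" else (-x, y)

    def side_for(self, orientation: str) -> str:
        if orientation == "normal":
            return self.base_side
        return "left" if self.base_side == "right" else "right"


@dataclass
class SimulatedTrial:
    trial: TrialRecord
    trace: Optional[GazeTrace]
    truth: EventSequence


# ------------------------------------------------------------------ design

def build_design(config: SimulatorConfig, rng: np.random.Generator
                 ) -> tuple[list[SceneDesign], dict[tuple[str, str], str]]:
    """Scene placements plus a counterbalanced subject x scene assignment.

    Scenes come in mirror pairs: members of a pair share |x| eccentricity
    and elevation, so left and right target sets have identical
    centre-distance distributions by construction. Subjects fall into four
    orientation groups; each subject sees every scene once, half with left
    and half with right targets, and across any group of four subjects each
    scene appears twice normal and twice mirrored.
    """
    if config.n_scenes % 2:
        raise ValueError("n_scenes must be even (scenes come in mirror pairs)")
    designs: list[SceneDesign] = []
    n_pairs = config.n_scenes // 2
    lo, hi = config.target_ecc_x_range
    ylo, yhi = config.target_y_range
    for k in range(n_pairs):
        ecc = rng.uniform(lo, hi)
        y = rng.uniform(ylo, yhi)
        designs.append(SceneDesign(f"sc{2 * k:03d}", "left", (-ecc, y)))
        designs.append(SceneDesign(f"sc{2 * k + 1:03d}", "right", (ecc, y)))

    assignment: dict[tuple[str, str], str] = {}
    for s in range(config.n_subjects):
        sid = f"s{s:02d}"
        group = s % 4
        for k in range(n_pairs):
            if group == 0:
                orient = "normal"
            elif group == 1:
                orient = "mirrored"
            elif group == 2:
                orient = "normal" if k % 2 == 0 else "mirrored"
            else:
                orient = "mirrored" if k % 2 == 0 else "normal"
            for j in (2 * k, 2 * k + 1):
                assignment[(sid, designs[j].scene_id)] = orient
    return designs, assignment


def validate_design(designs: Iterable[SceneDesign]) -> dict:
    """Compare target distances between left- and right-side sets.

    Returns means, mean differences and pooled-variance two-sample t
    statistics for the centre distance and the midline distance.
    """
    left = [d.target_center_deg for d in designs if d.base_side == "left"]
    right = [d.target_center_deg for d in designs if d.base_side == "right"]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least two scenes per side")

    def _cmp(a: np.ndarray, b: np.ndarray) -> dict:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        # identical paired sets have zero variance; define t = 0 there
        if not np.isfinite(t):
            t, p = 0.0, 1.0
        return {"mean_left": float(np.mean(a)), "mean_right": float(np.mean(b)),
                "difference": float(np.mean(a) - np.mean(b)),
                "t": float(t), "df": len(a) + len(b) - 2, "p": float(p)}

    lx, ly = np.array([c[0] for c in left]), np.array([c[1] for c in left])
    rx, ry = np.array([c[0] for c in right]), np.array([c[1] for c in right])
    return {
        "center_distance": _cmp(np.hypot(lx, ly), np.hypot(rx, ry)),
        "midline_distance": _cmp(np.abs(lx), np.abs(rx)),
    }


# ------------------------------------------------------------- event plan

def _gamma(rng, mean: float, cv: float) -> float:
    shape = 1.0 / cv ** 2
    return float(rng.gamma(shape, mean / shape))


def _lognormal(rng, mean: float, cv: float) -> float:
    sigma2 = math.log(1.0 + cv ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _is_leftward(theta: float) -> bool:
    return 90.0 < theta % 360.0 < 270.0


def _near_vertical(theta: float, margin: float = 0.5) -> bool:
    t = theta % 360.0
    return abs(t - 90.0) < margin or abs(t - 270.0) < margin


def _base_direction(rng, go_left: bool, cfg: SimulatorConfig) -> float:
    """Horizontal-concentrated direction within one hemifield, p_down below."""
    off = abs(rng.vonmises(0.0, cfg.base_direction_kappa))  # radians in [0, pi)
    off_deg = min(math.degrees(off), 89.5)
    down = rng.random() < cfg.p_down
    if go_left:
        return 180.0 + off_deg if down else 180.0 - off_deg
    return (360.0 - off_deg) % 360.0 if down else off_deg


def _sched_amp(rng, ordinal: int, cfg: SimulatorConfig) -> float:
    sched = cfg.amp_schedule
    mean = sched[min(ordinal - 1, len(sched) - 1)]
    return max(cfg.min_amplitude_deg, _gamma(rng, mean, cfg.amp_cv))


def _clamp_on_screen(x: float, y: float, geom: ScreenGeometry,
                     margin: float = 0.3) -> tuple[float, float]:
    hx = geom.width_deg / 2.0 - margin
    hy = geom.height_deg / 2.0 - margin
    return min(max(x, -hx), hx), min(max(y, -hy), hy)


def _endpoint(pos: tuple[float, float], end: tuple[float, float],
              cfg: SimulatorConfig) -> tuple[float, float]:
    """Clamp to the screen; keep every saccade above the amplitude floor.

    When clamping (or a short guided displacement) would leave the movement
    below ``min_amplitude_deg``, the saccade is redirected toward the screen
    centre at the floor amplitude instead, so the emitted event stays above
    the kinematic detection thresholds.
    """
    end = _clamp_on_screen(end[0], end[1], cfg.geometry)
    if math.hypot(end[0] - pos[0], end[1] - pos[1]) >= cfg.min_amplitude_deg:
        return end
    d = math.hypot(pos[0], pos[1])
    ux, uy = (-pos[0] / d, -pos[1] / d) if d > 1e-9 else (1.0, 0.0)
    return (pos[0] + ux * cfg.min_amplitude_deg,
            pos[1] + uy * cfg.min_amplitude_deg)


def _plan_saccade(ordinal: int, pos: tuple[float, float],
                  target: tuple[float, float], target_side: str,
                  p_left_trial: float, cfg: SimulatorConfig,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Return the saccade endpoint (deg) given the current position."""
    geom = cfg.geometry
    if ordinal == 1:
        # hemifield first: the marginal leftward probability is exact
        go_left = rng.random() < p_left_trial
        target_left = target[0] < 0.0
        if go_left == target_left and rng.random() < cfg.first_guidance:
            dx, dy = target[0] - pos[0], target[1] - pos[1]
            ang = math.atan2(dy, dx) + rng.vonmises(0.0, cfg.direction_noise_kappa)
            amp = max(cfg.min_amplitude_deg, math.hypot(dx, dy))
            theta = math.degrees(ang)
            if not (_near_vertical(theta) or _is_leftward(theta) != go_left):
                ex = pos[0] + amp * math.cos(ang)
                ey = pos[1] + amp * math.sin(ang)
                return _clamp_on_screen(ex, ey, geom)
        theta = math.radians(_base_direction(rng, go_left, cfg))
        amp = _sched_amp(rng, 1, cfg)
        ex = pos[0] + amp * math.cos(theta)
        ey = pos[1] + amp * math.sin(theta)
        return _clamp_on_screen(ex, ey, geom)

    gain = min(cfg.guidance_gain + cfg.guidance_step * (ordinal - 2),
               cfg.guidance_max)
    if rng.random() < gain:
        ex = target[0] + rng.normal(0.0, cfg.landing_sd_deg)
        ey = target[1] + rng.normal(0.0, cfg.landing_sd_deg)
        dx, dy = ex - pos[0], ey - pos[1]
        amp = math.hypot(dx, dy)
        if amp < cfg.min_amplitude_deg:  # enforce a detectable saccade
            scale = cfg.min_amplitude_deg / max(amp, 1e-12)
            ex, ey = pos[0] + dx * scale, pos[1] + dy * scale
        return _endpoint(pos, (ex, ey), cfg)
    theta = math.radians(_base_direction(rng, rng.random() < 0.5, cfg))
    amp = _sched_amp(rng, ordinal, cfg)
    ex = pos[0] + amp * math.cos(theta)
    ey = pos[1] + amp * math.sin(theta)
    return _endpoint(pos, (ex, ey), cfg)


def saccade_duration_ms(amplitude_deg: float) -> int:
    """Linear main sequence: 21 + 2.2 x amplitude, rounded to whole ms."""
    return max(2, round(21.0 + 2.2 * amplitude_deg))


def _fix_duration(rng, ordinal: int, cfg: SimulatorConfig) -> int:
    mean = (cfg.fixdur_start_ms
            + (cfg.fixdur_asymptote_ms - cfg.fixdur_start_ms)
            * (1.0 - math.exp(-cfg.fixdur_rate * ordinal)))
    return max(60, round(_lognormal(rng, mean, cfg.fixdur_cv)))


# --------------------------------------------------------------- one trial

def _trial_rng(seed: int, subject_index: int, scene_index: int
               ) -> np.random.Generator:
    """Per-trial substream: any trial is reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), subject_index, scene_index]))


def simulate_trial(design: SceneDesign, orientation: str, subject_id: str,
                   config: SimulatorConfig, rng: np.random.Generator,
                   render_samples: bool = True) -> SimulatedTrial:
    """Simulate one search trial.

    Returns the trial record, the raw 1 kHz binocular trace (or ``None``
    when ``render_samples`` is false) and the ground-truth event sequence.
    """
    cfg = config
    geom = cfg.geometry
    target_deg = design.center_for(orientation)
    target_side = design.side_for(orientation)
    tx_px, ty_px = deg_to_px(*target_deg, geom)
    half_w = cfg.aoi_width_deg / 2.0
    half_h = cfg.aoi_height_deg / 2.0
    box = AOIRect(
        float(deg_to_px(target_deg[0] - half_w, 0, geom)[0]),
        float(deg_to_px(0, target_deg[1] + half_h, geom)[1]),
        float(deg_to_px(target_deg[0] + half_w, 0, geom)[0]),
        float(deg_to_px(0, target_deg[1] - half_h, geom)[1]),
    )
    aoi = make_aoi(box, cfg.aoi_padding_deg, geom)

    p_left_trial = cfg.p_left(target_side)
    if cfg.item_logit_sd > 0.0:
        # per-scene deflection of the left bias, mirrored consistently
        scene_rng = np.random.default_rng(
            np.random.SeedSequence([hash(design.scene_id) % (2 ** 31)]))
        shift = scene_rng.normal(0.0, cfg.item_logit_sd)
        if target_side != design.base_side:
            shift = -shift
        logit = math.log(p_left_trial / (1 - p_left_trial)) + shift
        p_left_trial = 1.0 / (1.0 + math.exp(-logit))

    # --- plan the event timeline ------------------------------------
    fix0_dur = max(80, round(rng.gamma(cfg.fix0_shape,
                                       cfg.fix0_mean_ms / cfg.fix0_shape)))
    segments: list[dict] = []  # rendering plan in degree coordinates
    pos = (0.0, 0.0)
    t = fix0_dur  # onset of the first saccade
    segments.append({"kind": "fix", "t0": -cfg.pre_onset_ms, "t1": t,
                     "pos": pos})
    press: Optional[int] = None
    timed_out = False
    ordinal = 1
    while True:
        end = _plan_saccade(ordinal, pos, target_deg, target_side,
                            p_left_trial, cfg, rng)
        amp = math.hypot(end[0] - pos[0], end[1] - pos[1])
        sdur = saccade_duration_ms(amp)
        if t + sdur + 60 >= cfg.timeout_ms:
            # no room for another movement: hold fixation until timeout
            segments[-1]["t1"] = cfg.timeout_ms
            timed_out = True
            break
        segments.append({"kind": "sacc", "t0": t, "t1": t + sdur,
                         "start": pos, "end": end})
        t_fix = t + sdur
        on_target = aoi.contains(float(deg_to_px(*end, geom)[0]),
                                 float(deg_to_px(*end, geom)[1]))
        p_press = (cfg.p_recognize_on_target_fix if on_target
                   else cfg.p_false_press)
        if rng.random() < p_press and t_fix + cfg.motor_delay_ms < cfg.timeout_ms:
            press = t_fix + cfg.motor_delay_ms
            segments.append({"kind": "fix", "t0": t_fix, "t1": press + 1,
                             "pos": end})
            break
        fdur = _fix_duration(rng, ordinal, cfg)
        if t_fix + fdur >= cfg.timeout_ms:
            segments.append({"kind": "fix", "t0": t_fix, "t1": cfg.timeout_ms,
                             "pos": end})
            timed_out = True
            break
        segments.append({"kind": "fix", "t0": t_fix, "t1": t_fix + fdur,
                         "pos": end})
        pos = end
        t = t_fix + fdur
        ordinal += 1

    # --- blinks: invalid gaps inside sufficiently long fixations -----
    invalid_runs: list[tuple[int, int]] = []
    n_blinks = rng.poisson(cfg.blink_rate_per_trial)
    if n_blinks:
        pad = cfg.blink_pad_ms
        keep = pad + 60  # flanking fixation fragments stay detectable
        hosts = [i for i, s in enumerate(segments)
                 if s["kind"] == "fix" and s["t0"] >= 0
                 and (press is None or s["t1"] <= press - cfg.motor_delay_ms + 1)]
        rng.shuffle(hosts)
        for i in hosts[:n_blinks]:
            seg = segments[i]
            blen = round(rng.uniform(100, 300))
            if seg["t1"] - seg["t0"] < blen + 2 * keep:
                continue
            b0 = int(rng.integers(seg["t0"] + keep, seg["t1"] - keep - blen + 1))
            invalid_runs.append((b0, b0 + blen))
            seg["blink"] = (b0, b0 + blen)

    # --- ground-truth events (what an ideal parser reports) ----------
    events: list = []
    pad = cfg.blink_pad_ms
    for seg in segments:
        if seg["kind"] == "sacc":
            sx, sy = deg_to_px(*seg["start"], geom)
            ex, ey = deg_to_px(*seg["end"], geom)
            dx = seg["end"][0] - seg["start"][0]
            dy = seg["end"][1] - seg["start"][1]
            events.append(SaccadeEvent(
                ordinal=0, t_start=seg["t0"], t_end=seg["t1"],
                x_start=float(sx), y_start=float(sy),
                x_end=float(ex), y_end=float(ey),
                amplitude=math.hypot(dx, dy),
                direction=math.degrees(math.atan2(dy, dx)) % 360.0))
            continue
        x_px, y_px = deg_to_px(*seg["pos"], geom)
        if "blink" in seg:
            b0, b1 = seg["blink"]
            events.append(FixationEvent(0, seg["t0"], b0 - pad,
                                        float(x_px), float(y_px),
                                        blink_adjacent=True))
            events.append(BlinkEvent(b0 - pad, b1 + pad))
            events.append(FixationEvent(0, b1 + pad, seg["t1"],
                                        float(x_px), float(y_px),
                                        blink_adjacent=True))
        else:
            events.append(FixationEvent(0, seg["t0"], seg["t1"],
                                        float(x_px), float(y_px)))
    fix_n = 0
    sacc_n = 0
    for ev in events:
        if isinstance(ev, FixationEvent):
            ev.ordinal = fix_n
            fix_n += 1
        elif isinstance(ev, SaccadeEvent):
            sacc_n += 1
            ev.ordinal = sacc_n

    trial = TrialRecord(
        subject_id=subject_id, scene_id=design.scene_id,
        target_side=target_side, orientation=orientation, aoi=aoi,
        target_center=(float(tx_px), float(ty_px)),
        response_time_ms=press, timed_out=timed_out)

    trace = None
    if render_samples:
        trace = _render(segments, invalid_runs, cfg, rng)
    return SimulatedTrial(trial=trial, trace=trace,
                          truth=EventSequence(events))


def _render(segments: list[dict], invalid_runs: list[tuple[int, int]],
            cfg: SimulatorConfig, rng: np.random.Generator) -> GazeTrace:
    geom = cfg.geometry
    t0 = segments[0]["t0"]
    t1 = segments[-1]["t1"]
    n = t1 - t0
    t = np.arange(t0, t1, dtype=np.int64)
    x = np.empty(n)
    y = np.empty(n)
    for seg in segments:
        i0, i1 = seg["t0"] - t0, seg["t1"] - t0
        if seg["kind"] == "fix":
            x[i0:i1] = seg["pos"][0]
            y[i0:i1] = seg["pos"][1]
        else:
            # raised-cosine position profile over the saccade duration
            dur = seg["t1"] - seg["t0"]
            phase = 0.5 * (1.0 - np.cos(np.pi * np.arange(dur) / dur))
            x[i0:i1] = seg["start"][0] + (seg["end"][0] - seg["start"][0]) * phase
            y[i0:i1] = seg["start"][1] + (seg["end"][1] - seg["start"][1]) * phase
    x_px, y_px = deg_to_px(x, y, geom)
    jx = cfg.binocular_jitter_sd_deg / geom.deg_per_px_x
    jy = cfg.binocular_jitter_sd_deg / geom.deg_per_px_y
    if cfg.binocular_jitter_sd_deg > 0:
        xl = x_px + rng.normal(0.0, jx, n)
        yl = y_px + rng.normal(0.0, jy, n)
        xr = x_px + rng.normal(0.0, jx, n)
        yr = y_px + rng.normal(0.0, jy, n)
    else:
        xl, yl = x_px.copy(), y_px.copy()
        xr, yr = x_px.copy(), y_px.copy()
    valid = np.ones(n, dtype=bool)
    for b0, b1 in invalid_runs:
        valid[b0 - t0:b1 - t0] = False
    for arr in (xl, yl, xr, yr):
        arr[~valid] = np.nan
    return GazeTrace(t, xl, yl, xr, yr, valid.copy(), valid.copy())


# ------------------------------------------------------------- experiment

def simulate_experiment(config: SimulatorConfig, seed: int,
                        render_samples: bool = True,
                        n_subjects: Optional[int] = None) -> list[SimulatedTrial]:
    """Simulate a full counterbalanced session for every subject.

    A single master seed deterministically derives per-trial substreams, so
    any trial can be re-generated in isolation.
    """
    cfg = config if n_subjects is None else replace(config, n_subjects=n_subjects)
    design_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD5]))
    designs, assignment = build_design(cfg, design_rng)
    out: list[SimulatedTrial] = []
    for s in range(cfg.n_subjects):
        sid = f"s{s:02d}"
        for j, design in enumerate(designs):
            orient = assignment[(sid, design.scene_id)]
            rng = _trial_rng(seed, s, j)
            out.append(simulate_trial(design, orient, sid, cfg, rng,
                                      render_samples=render_samples))
    return out


def mirror_trial(sim: SimulatedTrial, geometry: ScreenGeometry) -> SimulatedTrial:
    """Globally mirrored twin of a simulated trial (x reflected, sides swapped)."""
    w = float(geometry.width_px)
    events = []
    for ev in sim.truth:
        if isinstance(ev, FixationEvent):
            events.append(replace(ev, x=w - ev.x))
        elif isinstance(ev, SaccadeEvent):
            events.append(replace(
                ev, x_start=w - ev.x_start, x_end=w - ev.x_end,
                direction=(180.0 - ev.direction) % 360.0))
        else:
            events.append(replace(ev))
    return SimulatedTrial(
        trial=sim.trial.mirrored(geometry),
        trace=None if sim.trace is None else sim.trace.mirrored(geometry),
        truth=EventSequence(events))
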