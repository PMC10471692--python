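import numpy as np
import pytest

from conftest import make_flat_trace
from scanbias.detect import DetectorParams, apply_exclusions, detect_events
from scanbias.simulate import SimulatorConfig, saccade_duration_ms, simulate_experiment
from scanbias.types import (AOIRect, EventSequence, FixationEvent, GazeTrace,
                            SaccadeEvent, TrialRecord)


def test_constant_position_is_one_fixation(geometry, detector_params):
    trace = make_flat_trace(2000)
    seq = detect_events(trace, detector_params, geometry)
    assert seq.counts() == (1, 0, 0)
    fix = seq.fixations[0]
    assert (fix.t_start, fix.t_end) == (-600, 1400)
    assert fix.ordinal == 0


def _trace_with_saccade(geometry, amplitude_deg=4.0, onset=400, n_ms=1500):
    """Fixation, one horizontal raised-cosine saccade, fixation."""
    dur = saccade_duration_ms(amplitude_deg)
    amp_px = amplitude_deg / geometry.deg_per_px_x
    x = np.full(n_ms, 300.0)
    phase = 0.5 * (1 - np.cos(np.pi * np.arange(dur) / dur))
    x[onset:onset + dur] = 300.0 + amp_px * phase
    x[onset + dur:] = 300.0 + amp_px
    t = np.arange(-100, n_ms - 100, dtype=np.int64)
    y = np.full(n_ms, 300.0)
    v = np.ones(n_ms, dtype=bool)
    trace = GazeTrace(t, x.copy(), y.copy(), x.copy(), y.copy(), v.copy(), v.copy())
    return trace, onset - 100, onset - 100 + dur  # true onset/offset in t units


@pytest.mark.parametrize("amplitude", [1.5, 4.0, 8.0])
def test_single_saccade_recovered(geometry, detector_params, amplitude):
    trace, t_on, t_off = _trace_with_saccade(geometry, amplitude)
    seq = detect_events(trace, detector_params, geometry)
    assert seq.counts() == (2, 1, 0)
    sacc = seq.saccades[0]
    assert abs(sacc.t_start - t_on) <= 4
    assert abs(sacc.t_end - t_off) <= 4
    assert sacc.amplitude == pytest.approx(amplitude, abs=0.1)
    assert sacc.direction == pytest.approx(0.0, abs=1.0)


def test_invalid_gap_becomes_padded_blink(geometry, detector_params):
    trace = make_flat_trace(2000)
    gap = slice(600 + 700, 600 + 850)  # 150 ms mid-fixation, t in [700, 850)
    for arr in (trace.x_left, trace.y_left, trace.x_right, trace.y_right):
        arr[gap] = np.nan
    trace.valid_left[gap] = False
    trace.valid_right[gap] = False
    seq = detect_events(trace, detector_params, geometry)
    assert seq.counts() == (2, 0, 1)
    blink = seq.blinks[0]
    assert (blink.t_start, blink.t_end) == (700 - 50, 850 + 50)
    assert all(f.blink_adjacent for f in seq.fixations)


def test_translation_invariance(geometry, detector_params):
    trace, _, _ = _trace_with_saccade(geometry, 4.0)
    shifted = GazeTrace(trace.t, trace.x_left + 57.0, trace.y_left - 31.0,
                        trace.x_right + 57.0, trace.y_right - 31.0,
                        trace.valid_left, trace.valid_right)
    a = detect_events(trace, detector_params, geometry)
    b = detect_events(shifted, detector_params, geometry)
    assert [(e.t_start, e.t_end) for e in a] == [(e.t_start, e.t_end) for e in b]


def test_timeline_is_a_partition(small_experiment, geometry, detector_params):
    for s in small_experiment[:20]:
        seq = detect_events(s.trace, detector_params, geometry)
        spans = sorted((e.t_start, e.t_end) for e in seq)
        assert spans[0][0] == s.trace.t[0]
        assert spans[-1][1] == s.trace.t[-1] + 1
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 == b0


def test_noise_free_ground_truth_agreement(geometry, detector_params):
    cfg = SimulatorConfig(n_subjects=2, n_scenes=50,
                          binocular_jitter_sd_deg=0.0)
    sims = simulate_experiment(cfg, seed=13)
    for s in sims:
        seq = detect_events(s.trace, detector_params, geometry)
        assert seq.counts() == s.truth.counts()
        for det, truth in zip(seq.saccades, s.truth.saccades):
            assert abs(det.t_start - truth.t_start) <= 4
            assert det.amplitude == pytest.approx(truth.amplitude, abs=0.1)


def test_short_trial_rejected(geometry, detector_params):
    with pytest.raises(ValueError):
        detect_events(make_flat_trace(3), detector_params, geometry)


def test_ordinals_anchor_at_scene_onset(small_experiment, geometry,
                                        detector_params):
    s = small_experiment[0]
    seq = detect_events(s.trace, detector_params, geometry)
    fix0 = [f for f in seq.fixations if f.ordinal == 0]
    assert len(fix0) == 1
    assert fix0[0].t_start <= 0 < fix0[0].t_end
    assert seq.saccades[0].ordinal == 1
    assert seq.saccades[0].t_start >= 0


# -------------------------------------------------------------- exclusions

def _five_fix_trial():
    """Five fixations; the press (at 1800 ms) falls in the last fixation."""
    events = []
    positions = [(400, 300), (300, 280), (500, 320), (-40, 300), (420, 310)]
    t = -600
    for k, pos in enumerate(positions):
        end = 250 if k == 0 else t + 400
        events.append(FixationEvent(k, t, end, *map(float, pos),
                                    offscreen=(pos[0] < 0)))
        if k < 4:
            events.append(SaccadeEvent(k + 1, end, end + 30,
                                       *map(float, pos), *map(float, positions[k + 1]),
                                       amplitude=3.0, direction=10.0))
            t = end + 30
    trial = TrialRecord("s01", "sc001", "left", "normal",
                        AOIRect(380, 280, 460, 340), (420.0, 310.0),
                        response_time_ms=1800, timed_out=False, correct=True)
    return EventSequence(events), trial


def test_offscreen_fixation_removed_at_every_stage():
    seq, trial = _five_fix_trial()
    for stage in ("generic", "duration_means", "duration_timecourse"):
        out = apply_exclusions(seq, trial, stage)
        assert all(not f.offscreen for f in out.fixations)


def test_duration_means_removes_first_last_and_press_fixation():
    seq, trial = _five_fix_trial()
    out = apply_exclusions(seq, trial, "duration_means")
    ordinals = [f.ordinal for f in out.fixations]
    # fixation 3 is off-screen; 0, 4 (last = press) are stage exclusions
    assert ordinals == [1, 2]


def test_duration_timecourse_keeps_rebased_fixation_zero():
    seq, trial = _five_fix_trial()
    out = apply_exclusions(seq, trial, "duration_timecourse")
    fix0 = [f for f in out.fixations if f.ordinal == 0]
    assert len(fix0) == 1
    assert fix0[0].t_start == 0  # duration re-based to scene onset
    assert fix0[0].duration == seq.fixations[0].t_end


def test_blink_adjacent_events_removed():
    seq, trial = _five_fix_trial()
    seq.fixations[1].blink_adjacent = True
    out = apply_exclusions(seq, trial, "generic")
    assert all(not f.blink_adjacent for f in out.fixations)


def test_empty_input_and_unknown_stage():
    assert len(apply_exclusions(EventSequence([]), None, "generic")) == 0
    with pytest.raises(ValueError, match="stage"):
        apply_exclusions(EventSequence([]), None, "nope")
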