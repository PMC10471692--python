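import math

import numpy as np
import pytest

from scanbias.bias import dichotomize_direction
from scanbias.geometry import px_to_deg
from scanbias.simulate import (SceneDesign, SimulatorConfig, build_design,
                               mirror_trial, simulate_experiment,
                               simulate_trial, validate_design)
from scanbias.scoring import build_analysis_set, score_response


def _first_saccades(sims):
    out = []
    for s in sims:
        sacc = [e for e in s.truth.saccades if e.t_start >= 0]
        out.append((s.trial.target_side, sacc[0]))
    return out


# ------------------------------------------------------------------ design

def test_design_counterbalancing_counts():
    cfg = SimulatorConfig(n_subjects=4, n_scenes=4)
    designs, assignment = build_design(cfg, np.random.default_rng(0))
    assert len(designs) == 4
    orientations = {}
    for s in range(4):
        sid = f"s{s:02d}"
        sides = []
        for d in designs:
            orient = assignment[(sid, d.scene_id)]
            sides.append(d.side_for(orient))
            orientations.setdefault(d.scene_id, []).append(orient)
        assert sides.count("left") == 2 and sides.count("right") == 2
    for scene_id, orients in orientations.items():
        assert orients.count("normal") == 2
        assert orients.count("mirrored") == 2


def test_mirrored_center_is_exact_reflection():
    d = SceneDesign("sc000", "left", (-5.0, -2.0))
    assert d.center_for("mirrored") == (5.0, -2.0)
    assert d.side_for("mirrored") == "right"


def test_paired_placement_matches_distances():
    cfg = SimulatorConfig()
    designs, _ = build_design(cfg, np.random.default_rng(1))
    left = [math.hypot(*d.target_center_deg) for d in designs
            if d.base_side == "left"]
    right = [math.hypot(*d.target_center_deg) for d in designs
             if d.base_side == "right"]
    assert abs(np.mean(left) - np.mean(right)) < 1e-12


def test_odd_scene_count_rejected():
    with pytest.raises(ValueError):
        build_design(SimulatorConfig(n_scenes=3), np.random.default_rng(0))


def test_validate_design_identical_paired_sets():
    cfg = SimulatorConfig(n_scenes=10)
    designs, _ = build_design(cfg, np.random.default_rng(2))
    report = validate_design(designs)
    assert report["center_distance"]["t"] == 0.0
    assert report["midline_distance"]["difference"] == pytest.approx(0.0)


def test_validate_design_hand_computed_t():
    designs = ([SceneDesign(f"L{i}", "left", (-x, 0.0))
                for i, x in enumerate((1.0, 2.0, 3.0))]
               + [SceneDesign(f"R{i}", "right", (x, 0.0))
                  for i, x in enumerate((4.0, 5.0, 6.0))])
    report = validate_design(designs)
    assert report["center_distance"]["t"] == pytest.approx(-3.674, abs=1e-3)


def test_validate_design_single_side_rejected():
    with pytest.raises(ValueError):
        validate_design([SceneDesign("a", "left", (-3.0, 0.0))] * 3)


# ----------------------------------------------------------------- trials

def test_symmetric_null_gives_half_leftward():
    cfg = SimulatorConfig(n_subjects=14, n_scenes=148,
                          p_left_L=0.5, p_left_R=0.5, p_down=0.5,
                          first_guidance=0.0)
    sims = simulate_experiment(cfg, seed=3, render_samples=False)
    lefts = [dichotomize_direction(s.direction) == "left"
             for _, s in _first_saccades(sims)]
    n = len(lefts)
    assert n >= 2000
    assert abs(np.mean(lefts) - 0.5) < 2 * math.sqrt(0.25 / n)


def test_perfect_searcher_hits_target_in_one_saccade(geometry):
    cfg = SimulatorConfig(n_subjects=2, n_scenes=24,
                          p_left_L=1.0, p_left_R=0.0,  # hemifield = target side
                          first_guidance=1.0, guidance_gain=1.0,
                          guidance_max=1.0, direction_noise_kappa=1e8,
                          landing_sd_deg=0.0, p_recognize_on_target_fix=1.0,
                          p_false_press=0.0, blink_rate_per_trial=0.0,
                          binocular_jitter_sd_deg=0.0)
    sims = simulate_experiment(cfg, seed=4)
    for s in sims:
        assert len(s.truth.saccades) == 1
        assert not s.trial.timed_out
        assert score_response(s.trial, s.trace)
        sacc = s.truth.saccades[0]
        tx, ty = px_to_deg(*s.trial.target_center, geometry)
        optimal = math.hypot(float(tx), float(ty))
        assert sacc.amplitude == pytest.approx(optimal, abs=1e-9)


def test_default_accuracy_matches_emulated_study():
    rates = []
    for seed in (21, 22, 23):
        sims = simulate_experiment(SimulatorConfig(), seed=seed)
        scored, acct = _score_all(sims)
        rates.append(acct.correct_rate)
    assert all(0.85 <= r <= 0.97 for r in rates)


def _score_all(sims):
    from dataclasses import replace
    scored = [replace(s.trial, correct=score_response(s.trial, s.trace))
              for s in sims]
    return scored, build_analysis_set(scored)[1]


def test_left_bias_parameter_recovery_binomial():
    # marginal leftward proportion equals the configured probability
    cfg = SimulatorConfig(n_subjects=14, n_scenes=148)
    sims = simulate_experiment(cfg, seed=5, render_samples=False)
    by_side = {"left": [], "right": []}
    for side, s in _first_saccades(sims):
        d = dichotomize_direction(s.direction)
        if d != "undefined":
            by_side[side].append(d == "left")
    for side, p in (("left", cfg.p_left_L), ("right", cfg.p_left_R)):
        obs = np.array(by_side[side])
        assert abs(obs.mean() - p) < 2 * math.sqrt(p * (1 - p) / len(obs))


def test_trace_stays_in_bounds(small_experiment, small_config):
    geom = small_config.geometry
    for s in small_experiment:
        assert s.trace.t[0] == -small_config.pre_onset_ms
        assert s.trace.t[-1] <= small_config.timeout_ms
        pre = s.trace.t < 0
        xd, yd = px_to_deg(s.trace.x_right[pre], s.trace.y_right[pre], geom)
        dist = np.hypot(xd, yd)
        assert np.nanmax(dist) <= 1.93


def test_master_seed_reproduces_trials(small_config):
    a = simulate_experiment(small_config, seed=9)
    b = simulate_experiment(small_config, seed=9)
    assert a[3].trial == b[3].trial
    assert np.array_equal(a[3].trace.x_left, b[3].trace.x_left, equal_nan=True)
    assert a[3].truth.counts() == b[3].truth.counts()


def test_mirror_trial_consistency(small_experiment, geometry):
    s = small_experiment[0]
    m = mirror_trial(s, geometry)
    assert m.trial.target_side != s.trial.target_side
    assert m.trial.target_center[0] == pytest.approx(
        geometry.width_px - s.trial.target_center[0])
    ok = s.trace.valid_left
    assert np.allclose(m.trace.x_left[ok],
                       geometry.width_px - s.trace.x_left[ok])
    for a, b in zip(s.truth.saccades, m.truth.saccades):
        assert b.direction == pytest.approx((180.0 - a.direction) % 360.0)
        assert b.amplitude == pytest.approx(a.amplitude)


def test_timeout_trials_are_flagged():
    cfg = SimulatorConfig(n_subjects=2, n_scenes=10,
                          p_recognize_on_target_fix=0.0, p_false_press=0.0)
    sims = simulate_experiment(cfg, seed=6, render_samples=False)
    assert all(s.trial.timed_out for s in sims)
    assert all(s.trial.response_time_ms is None for s in sims)
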