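import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_flat_trace
from scanbias.simulate import SimulatorConfig, mirror_trial, simulate_experiment
from scanbias.scoring import score_response
from scanbias.timecourse import (cousineau_morey_se, horizontal_deviation_curve,
                                 ordinal_curves)
from scanbias.types import AOIRect, TrialRecord


def _trial(sid, scid, side, rt):
    return TrialRecord(sid, scid, side, "normal",
                       AOIRect(100, 100, 200, 200), (150.0, 150.0),
                       response_time_ms=rt, timed_out=False, correct=True)


def _pairs_from_experiment(sims):
    from dataclasses import replace
    pairs = []
    for s in sims:
        if score_response(s.trial, s.trace):
            pairs.append((replace(s.trial, correct=True), s.trace))
    return pairs


def test_midline_gaze_gives_zero_curve(geometry):
    pairs = [(_trial(f"s{i}", "sc0", "left", 800), make_flat_trace(1400))
             for i in range(5)]
    curve = horizontal_deviation_curve(pairs, geometry, bootstrap_B=200,
                                       rng=np.random.default_rng(0))
    assert np.allclose(curve.mean_dev, 0.0)
    assert np.allclose(curve.ci_high - curve.ci_low, 0.0)
    assert len(curve.t) == 800


def test_mirrored_dataset_negates_curve(geometry):
    cfg = SimulatorConfig(n_subjects=4, n_scenes=16)
    sims = simulate_experiment(cfg, seed=17)
    pairs = _pairs_from_experiment(sims)
    pairs_m = _pairs_from_experiment([mirror_trial(s, geometry) for s in sims])
    a = horizontal_deviation_curve(pairs, geometry, bootstrap_B=200,
                                   rng=np.random.default_rng(5))
    b = horizontal_deviation_curve(pairs_m, geometry, bootstrap_B=200,
                                   rng=np.random.default_rng(5))
    assert len(a.t) == len(b.t)
    assert np.nanmax(np.abs(a.mean_dev + b.mean_dev)) < 1e-9
    # CIs swap roles under negation (same bootstrap draws)
    assert np.nanmax(np.abs(a.ci_low + b.ci_high)) < 1e-9


@pytest.mark.parametrize("seed", [31, 32, 33])
def test_default_simulation_shows_early_left_bias(geometry, seed):
    cfg = SimulatorConfig(n_subjects=6, n_scenes=30)
    pairs = _pairs_from_experiment(simulate_experiment(cfg, seed=seed))
    curve = horizontal_deviation_curve(pairs, geometry, bootstrap_B=200,
                                       rng=np.random.default_rng(seed))
    early = curve.mean_dev[:1000]
    assert np.nanmin(early) < 0.0          # an early leftward excursion
    assert np.nanmax(curve.mean_dev[1000:]) >= 0.0  # compensated later
    assert abs(curve.mean_dev[0]) < 0.5    # central fixation at onset


def test_curve_zero_at_onset_and_ci_contains_mean(geometry, small_experiment):
    pairs = _pairs_from_experiment(small_experiment)
    curve = horizontal_deviation_curve(pairs, geometry, bootstrap_B=300,
                                       rng=np.random.default_rng(2))
    ok = ~np.isnan(curve.mean_dev)
    assert np.all(curve.ci_low[ok] <= curve.mean_dev[ok] + 1e-12)
    assert np.all(curve.mean_dev[ok] <= curve.ci_high[ok] + 1e-12)
    assert abs(curve.mean_dev[0]) < 0.5


def test_pooled_equals_average_of_condition_curves(geometry):
    # one left and one right trial per subject, equal lengths
    rng = np.random.default_rng(3)
    pairs = []
    for i in range(6):
        for side, scid in (("left", "a"), ("right", "b")):
            trace = make_flat_trace(1400, x=400 + rng.normal(0, 30))
            pairs.append((_trial(f"s{i}", scid, side, 800), trace))
    kw = dict(bootstrap_B=100, rng=np.random.default_rng(0))
    pooled = horizontal_deviation_curve(pairs, geometry, **kw)
    left = horizontal_deviation_curve(pairs, geometry, condition="left", **kw)
    right = horizontal_deviation_curve(pairs, geometry, condition="right", **kw)
    avg = (left.mean_dev + right.mean_dev) / 2
    assert np.nanmax(np.abs(pooled.mean_dev - avg)) < 1e-9


def test_no_trials_rejected(geometry):
    with pytest.raises(ValueError):
        horizontal_deviation_curve([], geometry)


# ------------------------------------------------------- Cousineau-Morey

def test_cm_se_constant_within_subject_effect():
    se = cousineau_morey_se([[1.0, 3.0], [5.0, 7.0]])
    assert np.allclose(se, [0.0, 0.0])


def test_cm_se_crossed_case_hand_computed():
    se = cousineau_morey_se([[1.0, 3.0], [5.0, 3.0]])
    assert np.allclose(se, [1.414, 1.414], atol=1e-3)


def test_cm_se_missing_cells_rejected():
    with pytest.raises(ValueError):
        cousineau_morey_se([[1.0, np.nan], [2.0, 3.0]])


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_cm_se_invariances(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 2, size=(8, 2))
    se = cousineau_morey_se(y)
    shifted = y + rng.normal(0, 5, size=(8, 1))  # per-subject constants
    assert np.allclose(cousineau_morey_se(shifted), se)
    # M = 2: equals classical SE of the condition differences / sqrt(2)
    d = y[:, 0] - y[:, 1]
    classical = d.std(ddof=1) / np.sqrt(len(d))
    assert np.allclose(se, classical / np.sqrt(2))


# -------------------------------------------------------- ordinal curves

def test_perfect_searcher_has_single_saccade_ordinal():
    cfg = SimulatorConfig(n_subjects=4, n_scenes=16,
                          p_left_L=1.0, p_left_R=0.0, first_guidance=1.0,
                          guidance_gain=1.0, guidance_max=1.0,
                          direction_noise_kappa=1e8, landing_sd_deg=0.0,
                          p_recognize_on_target_fix=1.0, p_false_press=0.0,
                          blink_rate_per_trial=0.0)
    sims = simulate_experiment(cfg, seed=8, render_samples=False)
    curves = ordinal_curves(((s.trial, s.truth) for s in sims),
                            "saccade_amplitude")
    assert set(curves["ordinal"]) == {1}


def test_leftward_proportion_recovers_configured_bias():
    p = 0.7
    cfg = SimulatorConfig(n_subjects=10, n_scenes=60, p_left_L=p, p_left_R=p,
                          first_guidance=0.0)
    sims = simulate_experiment(cfg, seed=9, render_samples=False)
    curves = ordinal_curves(((s.trial, s.truth) for s in sims),
                            "leftward_proportion")
    row = curves[(curves.ordinal == 1) & (curves.condition == "pooled")]
    n = 10 * 60
    assert abs(float(row["mean"].iloc[0]) - p) < 2 * np.sqrt(p * (1 - p) / n)


def test_fixation_durations_rise_with_ordinal():
    cfg = SimulatorConfig(n_subjects=10, n_scenes=60)
    sims = simulate_experiment(cfg, seed=10, render_samples=False)
    curves = ordinal_curves(((s.trial, s.truth) for s in sims),
                            "fixation_duration")
    pooled = curves[curves.condition == "pooled"].set_index("ordinal")["mean"]
    assert pooled.loc[4] > pooled.loc[1]  # rises toward the asymptote


def test_observation_counts_decrease(small_experiment):
    curves = ordinal_curves(((s.trial, s.truth) for s in small_experiment),
                            "saccade_amplitude")
    pooled = curves[curves.condition == "pooled"].sort_values("ordinal")
    n = pooled["n_observations"].to_numpy()
    assert np.all(np.diff(n) <= 0)


def test_unknown_measure_rejected(small_experiment):
    with pytest.raises(ValueError, match="measure"):
        ordinal_curves([], "pupil_size")
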