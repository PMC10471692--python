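"""Quantify the leftward bias of the first saccade.

Simulates a full 22 x 148 experiment (event-level only, which is fast),
dichotomizes eligible first-saccade directions, and fits the two binomial
GLMMs of the analysis: a varying-intercept model for the overall left bias
and a dummy-coded model (right targets as reference, by-item random slope)
for the target-side modulation. Requires R with lme4 on PATH.
"""

import pandas as pd

from scanbias import (SimulatorConfig, compare_models, dichotomize_direction,
                      fit_mixed, inverse_logit, polar_histogram,
                      simulate_experiment)

sims = simulate_experiment(SimulatorConfig(), seed=5, render_samples=False)
rows = []
for s in sims:
    sacc = [e for e in s.truth.saccades if e.t_start >= 0][0]
    d = dichotomize_direction(sacc.direction)
    if d != "undefined":
        rows.append((s.trial.subject_id, s.trial.scene_id,
                     s.trial.target_side, sacc.direction, int(d == "left")))
df = pd.DataFrame(rows, columns=["subject", "item", "target_side",
                                 "angle", "left"])

hist = polar_histogram(df["angle"].to_numpy())
print(f"{len(df)} first saccades; histogram mass left of vertical: "
      f"{hist.left_mass():.3f}")

overall = fit_mixed(df, "left", coding=None)
b = overall.intercept
print(f"\nvarying-intercept GLMM: b = {b.b:.2f}, SE = {b.se:.2f}, "
      f"z = {b.stat:.2f} -> P(left) = {inverse_logit(b.b):.2f}")

dummy = fit_mixed(df, "left", coding="dummy_right_ref", item_slope=True)
no_slope = fit_mixed(df, "left", coding="dummy_right_ref")
print(f"dummy-coded GLMM (R-targets reference): "
      f"b = {dummy.intercept.b:.2f} (SE {dummy.intercept.se:.2f}); "
      f"L - R difference b = {dummy.effect('x').b:.2f} "
      f"(SE {dummy.effect('x').se:.2f})")
lrt = compare_models(no_slope, dummy)
print(f"random-slope LRT: delta chi2({lrt.df}) = {lrt.delta_chi2:.1f}, "
      f"p = {lrt.p:.3g}")
# With the default generator, the intercept recovers logit(0.670) ~ 0.71 and
# the difference recovers logit(0.774) - logit(0.670) ~ 0.52: the first
# saccade goes left more often than right, and more so for left targets.
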