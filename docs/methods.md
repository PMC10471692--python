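# Methods

This note documents the models, conventions and design choices behind
`scanbias`: what the pipeline computes, what the simulator does and does
not emulate, and where numerical decisions were genuinely open.

## Coordinate frames and geometry

Two frames are used. The *pixel frame* has its origin at the top-left
screen corner with y growing downward (tracker convention). The *degree
frame* has its origin at the screen centre with y growing upward, so a
saccade direction of 90° is upward and the "lower quadrants" are directions
in (180°, 360°). The default display is 800 × 600 px subtending
25.78° × 19.34° at 90 cm. Conversion is linear and anisotropic — the
horizontal and vertical px/deg factors are computed independently (they
differ in the fourth decimal) — and saccade amplitudes are Euclidean norms
in degree space. Conversions round-trip to well below 1e-9 px.

Raw-gaze analyses use the binocular average and require both eyes valid at
a sample; oculomotor (event-based) analyses use the right eye by default.
Response scoring follows the disjunctive rule: a response is correct if
the left eye, the right eye, *or* the binocular average lies in the padded
target AOI at the sample nearest the button press. "At the press" is read
literally as the nearest sample (a `window_ms` switch widens it); the
alternative reading — the whole fixation containing the press — was
rejected as less literal. AOI rectangles are half-open pixel intervals
([x0, x1) × [y0, y1)) so boundary membership is deterministic; the 0.75°
padding converts to pixels per axis and the padded box is clipped to the
screen. Timeout trials (no press within 15 s) count as errors; the
accounting also reports the correct rate with timeouts dropped from the
denominator, since either convention is defensible.

## Event detection

The detector replaces a proprietary tracker parser with an explicit
velocity/acceleration algorithm at the vendor's published "cognitive"
thresholds (30 °/s, 8000 °/s², 0.1° motion). Positions are smoothed with a
centred 5-sample moving average; velocity is a centred 5-point difference;
acceleration is the centred difference of speed. A run of samples at or
above the velocity threshold (ties count as saccadic, for determinism) is
confirmed as a saccade if its peak acceleration reaches the acceleration
threshold and the chord displacement exceeds the motion threshold. Onsets
are reported at the velocity crossing: on a raised-cosine saccade the
crossing sits 1–3 ms after the true onset regardless of amplitude, whereas
waiting for the displacement criterion would delay small-saccade onsets by
5 ms or more.

Runs of invalid samples become blinks, padded by 50 ms on each side
(lid-movement artefacts); padding is applied *before* fixation merging —
the order is a design choice, not a data fact. Complementary intervals are
fixations (centroid = mean raw position); fixation fragments shorter than
40 ms merge into their neighbouring saccades. 40 ms is below any plausible
real fixation, so merging only removes detector chatter. Events touching a
blink are flagged `blink_adjacent`; fixations with off-screen centroids are
flagged `offscreen`. The output tiles the trial: every sample belongs to
exactly one event. Fixation #0 is the fixation containing scene onset;
saccade ordinal 1 is the first saccade after onset.

Three exclusion stages serve the different analyses: `generic` drops
off-screen and blink-contaminated events; `duration_means` additionally
drops fixation #0, the trial's last fixation and the fixation containing
the button press; `duration_timecourse` keeps fixation #0 but re-bases its
duration to scene onset → first-saccade onset.

## First-saccade analysis

A trial contributes one observation if its chronologically *first*
post-onset saccade has amplitude > 1° and was launched within 1.93° of the
screen centre; there is no fallback to later saccades — "initial eye
movement" is read as the first movement, so a sub-threshold first saccade
excludes the trial. The 1.93° launch radius reuses the pre-trial
fixation-check radius, since the analysed central region has no other
stated size; both values are configurable. Directions are dichotomized
with strict inequalities (left: > 90° and < 270°); exact 90°/270° angles
are undefined and excluded. Polar histograms use 36 bins of 10° and are
normalised per degree (Σ density × bin width = 1), so histogram mass over
(90°, 270°) equals the dichotomized left proportion.

## Time course and ordinal curves

For each millisecond of a correct trial (scene onset up to the button
press), the horizontal deviation is the binocular-average x minus the
screen-centre x, in degrees, negative leftward. Trial curves are averaged
within subject over the trials still ongoing at t, subject curves are
averaged across subjects, and a percentile bootstrap that resamples
*subjects* with replacement (B = 2000 by default, seedable) gives the CI —
subjects, not trials, are the sampling unit of the averaging scheme.
Curves are reported up to the last millisecond at which at least half of
the subjects still contribute; the censoring rule is explicit, monotone
and configurable because search end-times vary and some horizon must be
chosen. Pre-onset samples are excluded; at t = 0 gaze sits at the central
fixation, so the curve starts near zero.

Ordinal-position curves summarise fixation durations (stage
`duration_timecourse`), saccade amplitudes and leftward-saccade
proportions (stage `generic`) by ordinal position, per subject and target
side. Condition means are means of subject means; the error bars are
Cousineau–Morey within-subject SEs across the two side conditions
(subject-mean-centred scores, grand mean added back, √(M/(M−1)) bias
correction; for M = 2 this equals the classical SE of the condition
differences divided by √2). Ordinals are truncated once either condition
has fewer than three contributing subjects.

## Search efficiency

`SPR = path / optimal`: the path is the summed amplitude of every saccade
completed up to and including the one landing in the first fixation whose
centroid lies in the padded target AOI (the same AOI as response scoring —
one AOI definition throughout); the optimal path is the degree-space
distance from screen centre to target centre. A single direct saccade to
the target gives SPR = 1 exactly. Trials that never fixate the AOI have
undefined SPR and are excluded with a count. Search time is scene onset to
button press.

## Mixed models

The analysis-defining parts of the (G)LMMs — contrast coding (dummy with a
declared reference level, or ±0.5 simple coding), crossed by-subject and
by-item random intercepts, optional by-item random slopes, the
log-likelihood comparison Δχ² = 2·(ℓ_large − ℓ_small) with a
parameter-count df — are constructed by this package. Numerical
optimisation is delegated to lme4 (`glmer`/`lmer` via `Rscript`), the
standard facility for crossed-random-effects GLMMs; fits use ML (not REML)
so log-likelihoods are comparable, with optimizer tolerances tightened so
reparameterised fits agree to ~1e-6. Gaussian fixed-effect p-values use a
normal approximation of t by default; `df_method="satterthwaite"`
delegates to lmerTest. Complete separation raises an explicit error;
negative likelihood-ratio differences (possible with approximate optima)
are clamped to zero with a warning. Conditional modes of the by-item
effects are exposed for exploring item-level heterogeneity.

## The synthetic scan-path generator

The generator produces the *conditions* the analyses assume: 22 subjects ×
148 scenes, 1 kHz binocular sampling, a 600 ms pre-onset central fixation
(within 1.93° of centre), and scan paths whose statistics carry the biases
of interest. Scenes come in mirror pairs sharing |eccentricity| and
elevation, so left and right target sets are distance-matched *exactly*;
four subject groups counterbalance orientation so each subject sees every
scene once, half left / half right, and each scene appears equally often
normal and mirrored across groups.

Per trial: fixation #0 has Gamma-distributed duration (mean 250 ms, shape
8). The **first saccade** draws its hemifield first — left with
probability `p_left_L` = 0.774 (left targets) or `p_left_R` = 0.670 (right
targets), the inverse logits of the condition estimates the GLMMs are
meant to recover — then a direction within that hemifield: with
probability 0.35 aimed at the target (von Mises noise, κ = 4) when the
target lies in the drawn hemifield, otherwise from a base distribution
concentrated near the horizontal with 0.6 of its mass below it (the
horizontal and downward biases). Drawing the hemifield first makes the
marginal leftward probabilities equal the configured values by
construction, which is what makes parameter recovery a sharp test; a
mixture that adds guidance *on top of* a left-biased base would shift the
marginals off the configured values. Later saccades are target-directed
with escalating probability (0.55 + 0.1 per ordinal, capped at 0.95) and
Gaussian landing error (SD 1°); non-guided amplitudes are Gamma-distributed
around a rise–plateau–fall schedule (first-saccade mean 4°). Fixation
durations are lognormal around 185 + 80·(1 − e^(−0.6·k)) ms, rising to a
265 ms asymptote. Saccade kinematics follow a raised-cosine position
profile with the classic linear main sequence (duration = 21 + 2.2·A ms);
any smooth monotone profile would do for the detector, and this one keeps
durations realistic.

Every generated saccade is kept at or above a 1.2° amplitude floor
(short re-fixation displacements are extended; endpoints clamped at the
screen edge are redirected toward the centre at the floor amplitude). On
the main sequence, a 1.2° saccade peaks near 78 °/s and 10 000 °/s², safely
above the detection thresholds, so the ground-truth contract — detected
event counts equal generated counts on noise-free traces — is achievable;
saccades much below 1° would be kinematically invisible to the thresholds
the detector is committed to.

Responses are AOI-contingent: a fixation inside the target AOI triggers a
press with probability 0.85 after a 500 ms motor delay (the fixation
extends to the press, as observers keep looking at a found target). A
fixation on a distractor triggers a false press with probability 0.06 —
the generator's error mechanism, calibrated by Monte Carlo so overall
accuracy sits near the 92% of the emulated easy search task. Trials time
out at 15 s. Blinks (Poisson, 0.3/trial, 100–300 ms) are inserted into
fixations long enough that the padded blink leaves detectable flanking
fragments; per-eye positions are the shared gaze plus independent Gaussian
jitter (SD 0.05°). A single master seed derives per-trial substreams, so
any trial is reproducible in isolation.

**What the simulator does not emulate.** Scene content (salience, gist,
semantics) and the resulting item-level heterogeneity of the left bias are
absent by default; an optional per-scene logit deflection
(`item_logit_sd`, off by default) provides crude heterogeneity but no
"cognitive override" structure, so by-item random-slope variances fitted
on default synthetic data collapse to ~0 (singular fits are expected and
flagged, not errors). Calibration failures and lost trials are not
simulated. Simulated searches are faster (≈1.2 s mean) than typical human
scene search (≈2.5 s) because guidance is memoryless and spatially exact;
consequently scan-path ratios are lower than human values. Passing tests
therefore certify the *analysis machinery* — detection, exclusion rules,
averaging, bootstrap calibration, contrast recovery, mirror symmetry — not
the realism of human scan-path statistics.

## Numerical conventions and edge cases

- At-threshold velocity samples classify as saccadic (deterministic
  boundary).
- AOI membership uses half-open intervals; enlarging an AOI can never flip
  a correct response to incorrect.
- Bootstrap draws with zero contributing subjects at a late millisecond
  yield NaN and are ignored by the percentile; the reported horizon
  (≥ 50% of subjects) keeps such points out of the curve anyway.
- `validate_design` defines t = 0 for identical zero-variance sets (the
  mirror-paired case).
- Degenerate generator configurations (guidance 1, noise 0, recognition 1)
  produce exact single-saccade trials and are used as closed-form oracles
  in the tests.
- Problem sizes in the test suite are scaled to the check at hand: 500
  noise-free trials for detector equivalence, 20 seeded replications of
  the full 22 × 148 design for GLMM recovery, 500 replications × B = 500
  for bootstrap coverage, 6 × 40 sessions for the mirror-symmetry suite.

## Known limitations

- Binomial GLMM p-values are Wald z-tests; Gaussian p-values default to a
  normal approximation (Satterthwaite available via lmerTest). Profile or
  parametric-bootstrap intervals are not implemented.
- The detector has no microsaccade or pupil handling, and binocular
  processing is limited to averaging.
- lme4 via Rscript adds ~1–2 s process overhead per fit; batch fitting in
  one R session would amortise it but is not implemented.
- The simulator's guidance model is memoryless (no inhibition of return,
  no systematic scan strategies), and blink placement avoids the response
  window by construction.
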