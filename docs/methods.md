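# Methods

This note documents the models, parameter choices and numerical decisions
behind `runfatigue`, and what the synthetic-data generator does and does
not emulate.

## Analysis pipeline

The unit of analysis is one runner performing an incremental treadmill
test to exhaustion: 3-min stages, +0.28 m/s per stage, starting near 85%
of 10-k race pace (2.5–3.61 m/s across runners). Three synchronised
streams are recorded: vertical ground reaction force (GRF) at 516 Hz,
two 6-DoF trunk IMUs (C7 and L5) at 218 Hz of which the gyroscopes are
used, and breath-by-breath V̇O2/V̇CO2/V̇E.

### Signal conditioning

* **Filtering.** Force and angular velocity are low-pass filtered with a
  2nd-order Butterworth at 30 Hz and 15 Hz respectively. Filtering is
  applied forward–backward (zero phase) so contact-relative timing is
  unbiased; the price is that the effective attenuation is the *squared*
  magnitude response (a sine at the nominal cutoff emerges at ~0.50
  amplitude rather than 0.71). Angular velocity is filtered *before*
  integration.
* **Breath smoothing.** A centred 11-breath moving average per gas
  channel; at the series edges the window shrinks symmetrically. Breath
  times are never altered.
* **Gyroscope integration.** Cumulative trapezoidal integration per axis,
  initial angle 0. Drift is removed by fitting and subtracting a single
  ordinary-least-squares line (angle vs time) over the whole trial; this
  is exact when the drift source is a constant gyro bias, and idempotent.
  A per-stage detrend was considered and rejected as a default: a single
  global line is the most literal least-squares correction and leaves
  within-step ranges untouched.

### Footfalls and features

Contacts are maximal runs of filtered force above 40 N, refined by
walking each boundary to the nearest sample where the discrete gradient
changes sign (the local curve minimum). Two gates suppress threshold
chatter: minimum stance 80 ms, minimum flight 30 ms (runs separated by
less gets merged). Note that zero-phase filtering spreads a stance onset
by a few samples; the refinement lands on the filtered waveform's own
minimum, which is the consistent definition for every step.

Per step (one contact start to the next), ten features: GRF_peak
(max force / body mass, N·kg⁻¹), I_total (trapezoidal impulse over the
contact, N·s, deliberately not mass-normalised although GRF_peak is —
the two features carry the units conventional for each),
RFD_maxD and RFD_avgD (max and mean of the loading-rate curve from
contact start to the force-peak sample; the curve is the central finite
difference of force, reported in kN·s⁻¹), and six angular-displacement
ranges (max − min of the drift-corrected angle) at C7 and L5 about the
vertical-rotation, flexion/extension and lateral-flexion axes. Angular
ranges use the full step window rather than stance only, because trunk
motion is not confined to ground contact; IMU streams are resampled onto
the force clock by linear interpolation. A step whose force peak falls on
the first contact sample has no defined loading phase and is rejected
with a logged warning.

### VT2 detection and labeling

The second ventilatory threshold is detected automatically as the
breakpoint of a continuous two-segment piecewise-linear model of V̇E as a
function of V̇O2 (the V-slope family): for every candidate breath on a
grid over the interior of the series (first/last 10% excluded), a hinge
regression is fitted by least squares; the candidate minimising total SSE
wins, ties going to the earliest breath (conservative: more post-VT2
data). A detection requires the post/pre slope ratio to be ≥ 1.1 —
single-slope data raise an explicit no-threshold error. The V̇E/V̇O2 and
V̇E/V̇CO2 ventilatory-equivalent curves are exposed as diagnostics only.
In laboratory practice this decision is made by human raters; the
automated detector replaces them with the most literal reading of
"over-proportional increase of V̇E vs V̇O2".

Steps more than 20 s before VT2 are labeled *pre*, more than 20 s after
*post*; the ±20 s band is excluded. Labeling is a strict partition. Then,
per feature and per 3-min stage, the stage-local mean and sample SD are
computed once (including candidate outliers — a single pass); values
outside ±3 SD are replaced by the value of the temporally nearest
same-stage in-bounds point (exact-distance ties go to the earlier point).
On clean Gaussian data this touches ~0.3% of values.

### Subject-specific model

Per runner: stratified 80/20 train/test split; if the training class
ratio exceeds 1.5 (the "large disparity" threshold, configurable), the
majority class is randomly under-sampled to the minority count. A grid
search over forest size {100, 250, 500, 1000} and features-per-split
{1, 2, 3, 5} (≈√10 = 3 is the conventional default for ten features)
minimises out-of-bag error; ties prefer the cheaper model. Recursive
feature elimination then starts from all ten features and repeatedly
drops the feature whose removal maximises ten-fold cross-validated
accuracy, reusing the same fold partition for every subset comparison to
reduce variance, down to two features; the subset with the best CV
accuracy overall is kept, ties resolved toward the larger subset. The
candidate-subset forests may be configured smaller than the tuned model
(`rfe_n_trees`, `rfe_max_samples`) — only the *ranking* of subsets uses
them; the final forest is always refit at the tuned settings on the full
balanced training set, and all metrics come from the untouched test
split. Test rows are never visible to balancing, tuning or elimination.

Metrics (positive class = post-VT2): accuracy with an exact
Clopper–Pearson 95% binomial CI, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), F1 = 2TP/(2TP+FP+FN), and Cohen's κ = (p_o − p_e)/(1 − p_e).
Every reported metric is recomputable from the stored confusion matrix.

### TreeSHAP

Attributions use the exact polynomial-time path-dependent TreeSHAP
algorithm for tree ensembles, implemented in `_treeshap.py` (numba) and
validated against brute-force Shapley enumeration with tree-path-
dependent conditional expectations. No background dataset is involved:
absent features are marginalised over each split's training cover, the
original TreeSHAP formulation. Attributions are on the probability-of-
post scale, so values above zero push the prediction toward the post-VT2
class; local accuracy (base value + attribution row = predicted
probability) is asserted for every observation at 1e−6. Explanations are
computed on the test partition. Importance proportions are mean |SHAP|
per feature normalised to sum to one; an all-zero matrix (constant model)
degrades to uniform proportions with a warning. Dependence tables carry
one row per observation plus a per-stage summary of the SD of SHAP
within narrow (decile) feature-value bins — the vertical-dispersion
statistic that flags interaction effects.

## The synthetic generator

The generator produces recordings with the statistical structure the
pipeline assumes, plus ground truth (planted VT2 time, per-step true
feature values) so that every stage is testable.

* **Stance waveform**: the sum of two raised-cosine lobes — an impact
  lobe peaking at 1.6 BW 25 ms after contact (half-width 25 ms) and an
  asymmetric active lobe peaking near mid-stance at 2.2–2.8 BW. This is
  the standard rearfoot-running GRF shape and yields non-trivial loading
  rates. Flight force is exactly zero before sensor noise (white,
  1.5 N SD, clipped so force never goes negative).
* **Gait timing**: cadence 2.6–3.0 steps/s and duty factor 0.35–0.31
  across the 2.5–5.0 m/s velocity range, with 1% step-period jitter.
  Cadence and stance times are not reported for the original cohort;
  these are literature-typical values.
* **Trunk motion**: per axis, the angle is a sinusoid at step frequency
  whose per-step amplitude (C7: 4/2.5/3°, L5: 5/4/4.5° half-range for
  vertical rotation / flex-ext / lateral flexion) directly equals half
  the extracted range; the gyro stream is its analytic derivative plus a
  constant 0.5 deg/s bias per axis (making least-squares drift removal
  exactly correct in the noise-free limit) and 1 deg/s white noise.
* **Breaths**: V̇O2 follows the stage velocity profile through
  first-order kinetics (τ = 30 s, economy ≈ 10 + 12·v mL·kg⁻¹·min⁻¹)
  plus a slow-component drift of 1.2 mL·kg⁻¹·min⁻¹ per minute — the
  textbook heavy-intensity behaviour, which also keeps V̇O2 strictly
  increasing within stages so that the *time* of the V-slope breakpoint
  is identifiable. V̇E is piecewise-linear in V̇O2 (ventilatory equivalent
  ≈ 25 below VT2, slope ratio 1.8 above); V̇CO2 tracks an RER ramp
  0.85 → 1.15; all channels carry 1.5% multiplicative breath noise,
  consistent with smoothed curves on which human raters can pinpoint a
  threshold time.
* **Effect injection** happens at the waveform-parameter level only
  (e.g. a planted RT_APu shift scales the C7 lateral-flexion amplitude;
  an RFD_maxD shift scales the impact lobe), never by editing extracted
  features, so the full chain is exercised. Shifts are expressed in
  units of the feature's step-to-step SD at fixed velocity; since every
  feature is proportional to its parameter, a shift of *d* multiplies
  the parameter by (1 + d·σ_rel). Onset is a step at VT2 or a linear
  ramp to test end (emulating a dispersed transition phase); a shift can
  additionally be gated to later stages, which plants a feature
  interaction.
* **Velocity coupling** is a single dial (`EffectSpec.velocity_coupling`):
  at 1.0 (default) waveform parameters follow belt velocity as above —
  the physiological regime, where running mechanics change with
  intensity; at 0.0 every parameter is frozen at its start-velocity
  value, making the ten features strictly stationary. `EffectSpec.null()`
  (zero shifts, zero coupling) is the null configuration under which a
  correct pipeline must classify at chance; the property tests for
  monotone effect injection, learnability and importance ranking also
  use the stationary regime so the planted effect is the only signal.
* **Ground truth**: per-step true force features are computed by
  rendering each stance in isolation (zero-padded, on the trial's own
  sampling-grid phase), passing it through the same 30 Hz filter spec,
  and applying the feature definitions directly. The truth therefore
  reflects ideal single-stance processing — independent of trial
  assembly, detection and windowing — while sharing the definitional
  filter, without which loading-rate truths would be unreachable (the
  30 Hz low-pass attenuates RFD_maxD by ~15%). Trunk-range truths are
  exactly twice the planted amplitudes.
* **Cohorts** draw per-subject start velocity (2.5–3.61 m/s), completed
  stages (5–7, which lands per-subject step counts in the 2347–3577
  range of the original datasets), body mass (N(78.85, 6.89) kg) and
  VT2 fraction (0.55–0.75 of test duration) from a dedicated stream;
  per-subject seeds derive from the master seed via a counter-based
  `SeedSequence` spawn recorded in the output metadata.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no horizontal GRF, no anthropometric or
musculoskeletal structure, no stride-to-stride long-range correlations
or fatigue-related variability growth, no breathing entrainment to
cadence, no soft-tissue or treadmill-frame resonances, and sensor noise
that is white rather than structured. Results on this generator validate
the *pipeline machinery* (detection, extraction, labeling, model and
attribution logic), not biomechanical conclusions about runners.

## Problem sizes and tolerances

* Unit and property tests run on 2–3-stage subjects (6–9 min, ~900–1500
  steps) — large enough for stable statistics, small enough for a quick
  suite. Monte-Carlo checks use the replicate counts their statements
  name (e.g. 50 seeds for VT2 recovery, 20 for importance ranking).
* The benchmark script (`scripts/acceptance.py`) runs 2 cohorts × 13
  subjects at the full cohort defaults; its tuning stage uses the
  reduced grid {100, 250} × {2, 3} and 30-tree/256-sample elimination
  forests. The elimination stage is the dominant cost (53 subset
  evaluations × 10 folds per subject); the reduced settings change the
  selected subsets only marginally and the final model is always refit
  at the tuned settings.
* Numerical tolerances: noise-free extraction matches generator truth to
  2% (the residual is sampling-phase and interpolation error); footfall
  boundaries match the generated schedule to ≤ 2 samples on the
  noise-free signal; SHAP local accuracy holds to 1e−6 (observed:
  ~1e−15); breakpoint recovery is required within ±30 s in ≥ 90% of
  noisy seeds.
* Degenerate inputs fail loudly: sub-Nyquist-violating cutoffs, even
  smoothing windows, non-finite gyro samples, single-slope breath data,
  labelings that empty a class, and feature mismatches in the explainer
  all raise typed errors. A stage whose every value is flagged by the
  outlier rule is left unchanged with a warning.

## Known limitations

* The V-slope detector assumes a single breakpoint; respiratory
  compensation or VT1 structure in real data could attract the fit.
* The ±3 SD outlier rule uses a single pass with the candidate included,
  which slightly inflates the stage SD for strong outliers (matching the
  one-shot description it implements).
* Recursive elimination evaluates one-feature-at-a-time removals; it is
  greedy and can keep redundant feature pairs.
* With velocity coupling enabled, intensity-driven and fatigue-driven
  feature changes are intentionally confounded — exactly as in a real
  incremental protocol, where belt velocity and fatigue rise together.
  The stationary regime exists to separate the two in tests.
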