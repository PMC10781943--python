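# runfatigue

Subject-specific classification of running fatigue state from treadmill
biomechanics.

## The problem

During an incremental treadmill run to exhaustion (3-min stages, +0.28 m/s
per stage), a runner's mechanics change as fatigue accumulates. The second
ventilatory threshold (VT2) — the intensity at which minute ventilation V̇E
starts rising over-proportionally to oxygen uptake V̇O2 — marks the
metabolic transition beyond which fatigue effects concentrate. This package
implements, per runner:

1. **Signal conditioning** — zero-phase 2nd-order Butterworth low-pass
   filtering (30 Hz force, 15 Hz angular velocity), 11-breath moving-average
   smoothing of gas-exchange data, gyroscope integration with least-squares
   drift removal.
2. **Per-step features** — footfalls detected on the vertical ground
   reaction force (40 N threshold refined by a gradient walk to the curve
   minima), then ten features per step:

   | feature | definition | units |
   |---|---|---|
   | GRF_peak | max force per contact / body mass | N·kg⁻¹ |
   | I_total | ∫ F dt over the contact (impulse) | N·s |
   | RFD_maxD | max dF/dt from contact start to the force peak | kN·s⁻¹ |
   | RFD_avgD | (F_peak − F_start)/(t_peak − t_start) | kN·s⁻¹ |
   | RT_LTu, RT_MDu, RT_APu | C7 angular range per step: vertical rotation, flex/ext, lateral flexion | deg |
   | RT_LTlo, RT_MDlo, RT_APlo | the same three ranges at L5 | deg |

3. **VT2 labeling** — an automated V-slope breakpoint detector (continuous
   two-segment least-squares fit of V̇E vs V̇O2; the breakpoint minimising
   SSE, requiring a post/pre slope ratio ≥ 1.1) splits steps into pre/post
   classes, a ±20 s window around VT2 is excluded, and per-stage ±3 SD
   outliers are replaced by their nearest in-bounds neighbour.
4. **Subject-specific random forest** — stratified 80/20 split, random
   under-sampling of the majority class, grid search over forest size and
   features-per-split by out-of-bag error, recursive feature elimination
   under ten-fold cross-validated accuracy, and the full metric suite on
   the held-out 20%: accuracy with exact (Clopper–Pearson) 95% CI, Cohen's
   κ = (p_o − p_e)/(1 − p_e), sensitivity, specificity, F1 (positive class
   = post-VT2).
5. **TreeSHAP interpretation** — exact path-dependent TreeSHAP attributions
   on the probability scale (implemented in this package and verified
   against brute-force Shapley enumeration), mean-|SHAP| importance
   proportions, and dependence tables with a within-bin dispersion summary
   that flags feature interactions.

Because the original laboratory recordings are not publicly deposited, a
first-class **synthetic-data module** generates recordings with known
ground truth — two-lobe raised-cosine stance waveforms at running
magnitudes, stride-periodic trunk angular velocity with constant gyro bias
and white noise, and breath series with a planted V-slope breakpoint —
with configurable post-VT2 effect sizes injected at the waveform-parameter
level so the entire extraction chain is exercised.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_subject_model.py` (a 4-stage subject with post-VT2
shifts of +1.0 SD on RT_APu, +0.75 on RFD_maxD, +0.5 on RT_LTu) prints:

```
accuracy    : 0.848 (95% CI 0.807-0.882)
kappa       : 0.682
sensitivity : 0.857   (post-VT2 recognised)
specificity : 0.842   (pre-VT2 recognised)
F1          : 0.808
tuned       : {'n_trees': 100, 'max_features': 2}, 8 features kept
balance     : {'pre': 932, 'post': 560} -> {'pre': 560, 'post': 560}
```

i.e. for this runner the forest recognises the post-VT2 state in ~85% of
held-out steps, well beyond the κ≈0 of a chance classifier. The companion
`examples/05_explain_model.py` attributes the predictions:

```
importance proportions (mean |SHAP|, normalised):
 feature  mean_abs_shap  proportion  rank
  RT_APu       0.172288    0.304865     1
GRF_peak       0.099838    0.176664     2
RFD_maxD       0.083467    0.147696     3
```

The planted dominant feature (upper-trunk lateral flexion range, RT_APu)
carries ~30% of the total attribution, and the within-bin SHAP dispersion
grows in the stages around VT2 (0.037 → 0.051), the signature of feature
interactions during the transition phase.

A cohort run (`examples/06_cohort_run.py`) aggregates one such model per
runner into a results table with one row per subject.

## Command line

The same pipeline is exposed as a thin CLI:

```bash
runfatigue simulate --seed 1 --out rec/            # write grf/imu/breaths CSVs
runfatigue extract rec/ --out steps.csv
runfatigue label rec/ steps.csv --out labeled.csv
runfatigue train labeled.csv --out report.json
runfatigue run-all --subjects 13 --seed 1 --out cohort_out/
```

## Layout

```
src/runfatigue/
  simulate.py    synthetic recordings with ground truth (+ CSV round trip)
  signal.py      filtering, breath smoothing, integration, drift removal
  gait.py        footfall detection and the ten per-step features
  vt2.py         V-slope breakpoint, labeling, outlier replacement
  model.py       balancing, OOB tuning, recursive elimination, metrics
  _treeshap.py   exact path-dependent TreeSHAP (numba)
  explain.py     SHAP results, importance proportions, dependence tables
  pipeline.py    per-subject / cohort orchestration, YAML config
  cli.py         click front end
docs/methods.md  model assumptions, parameter choices, limitations
examples/        one narrative script per capability
tests/           pytest suite (unit, property and acceptance tests)
```
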