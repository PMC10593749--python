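# bootgait

Wearable-sensor monitoring of Achilles tendon load and walking speed during
immobilizing-boot gait.

## The problem

Patients recovering from Achilles tendon injury walk in an immobilizing boot
whose heel wedges (30°, 5°, 0°) progressively re-load the healing tendon.
Clinicians would like to monitor that loading continuously, but lab-grade
instrumented insoles are expensive and burdensome. A cheap body-worn IMU
(3-axis accelerometer + 3-axis gyroscope, nominally 100 Hz) on the boot does
not measure load directly — but stride-level statistics of its signals carry
enough information to *predict* peak tendon load and walking speed through a
sparse linear model.

`bootgait` implements that monitoring pipeline end to end:

1. **Segmentation** — gait cycles are cut from the insole's total plantar
   force by a 50 N contact threshold: heel strike and toe-off are the
   threshold crossings bounding each stance, and a stride runs heel strike to
   heel strike.
2. **Features** — for every stride and IMU channel *x(t)*: max, min,
   absolute impulse ∫|x| dt, stance impulse ∫_stance x dt and swing impulse
   ∫_swing x dt, plus stance and swing time from the insole (6 channels × 5
   stats + 2 times = 32 features for one sensor).
3. **Targets** — peak Achilles load per stride, expressed in body weights
   (BW) via a configurable lever-ratio stand-in for a physics-based
   insole-to-tendon model; strides peaking under 0.5 BW are excluded.
   Walking speed is the net forward center-of-mass progression divided by
   elapsed time, per trial.
4. **Model** — LASSO regression: ŷ = β₀ + Σⱼ βⱼ zⱼ on z-scored features with
   an L1 penalty selected by inner 5-fold CV minimizing MAPE
   (100·mean|ŷ−y|/y). Agreement is graded *excellent* (< 10 % MAPE) or
   *acceptable* (< 20 %).
5. **Evaluation** — three training paradigms per wedge condition and target:
   *generalized* (leave-one-subject-out), *hybridized* (others' data + half
   the test subject's strides) and *personalized* (only half the subject's own
   strides); plus sensor ablations (no gyroscope, 50/25 Hz decimation,
   multi-sensor), learning curves, and a lag-scanned normalized
   cross-correlation score for dual-sensor agreement.

Because public stride-level recordings are not available, the package ships a
first-class synthetic cohort generator (`bootgait.synthetic`) that emulates
the statistical structure the models assume — stride-periodic signals whose
amplitude/timing features are linear in walking speed, condition-dependent
loading (0° > 5° > 30°), subject-specific load offsets invisible to the IMU,
and within-subject noise — with full ground truth for validation.

## Worked example

```python
import bootgait as bg

cohort = bg.generate_cohort(bg.SimConfig(seed=1))          # 840 trials, 5880 strides
dataset, audit = bg.build_stride_dataset(cohort.trials)    # segment + features + targets
# audit: 5880 strides segmented, 156 dropped under 0.5 BW, 5724 kept

kept = dataset[(dataset.condition_deg == 0) & dataset.kept]
train = kept[kept.subject_id != "S01"]                     # leave subject S01 out
test = kept[kept.subject_id == "S01"]

model = bg.StrideLassoModel.from_dataframe(train, target="at_peak_bw")
results = model.fit(bg.ModelConfig(seed=0))
print(results.summary(top=6))
```

```
              Stride LASSO Regression Results
==============================================================
No. observations:       1764    Selected penalty: 2.23227e-05
Features:                 32    Nonzero coefs:    31
Inner-CV MAPE:       13.163%    Grade:            acceptable
--------------------------------------------------------------
feature                                    coef (std. units)
--------------------------------------------------------------
(intercept)                                          2.07293
boot_gyr_ml_abs_impulse                             -6.79267
boot_gyr_ml_swing_impulse                            4.80377
stance_time_s                                       -4.26971
boot_acc_si_stance_impulse                           2.95899
boot_gyr_ml_stance_impulse                          -1.92424
boot_acc_si_max                                     -1.53066
==============================================================
```

The fitted model predicts the held-out subject's stride loads with 8.59 %
MAPE. Running the full leave-one-subject-out paradigm at 0° aggregates this
across all ten subjects:

```python
gen = bg.evaluate_generalized(dataset, 0, "at_peak_bw")
print(f"{gen.mape_mean:.1f} +/- {gen.mape_sd:.1f}% ({gen.grade})")
# 14.2 +/- 7.5% (acceptable)
```

The interpretation: generalized tendon-load models are limited by
subject-specific load offsets that no boot-IMU feature encodes, whereas
personalized models absorb them — on the same cohort the personalized 0°
load MAPE is ~3–4 %, and walking speed (a kinematic quantity the features
encode directly) is predicted at ~2 % MAPE even without any subject-specific
training data.

## Command line

```bash
bootgait --config run.yaml simulate     # write a synthetic cohort
bootgait --config run.yaml extract      # recordings -> features.csv (+ attrition log)
bootgait --config run.yaml evaluate     # 3 conditions x 3 paradigms x 2 targets
bootgait --config run.yaml ablate       # sensor-configuration grid
bootgait --config run.yaml learning-curve
```

See `tests/test_cli.py` for a minimal YAML config. One global `seed` drives
every stochastic stage through named substreams; identical config + seed
reproduces `results.csv` byte for byte.

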