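# Methods

## Signal model and processing chain

A trial is one walking pass in an immobilizing boot with synchronized
streams sharing t = 0: six-axis IMU channels per body location (accelerometer
in m/s², gyroscope in deg/s; axes superior–inferior, anterior–posterior,
medial–lateral), the total plantar force from an instrumented insole (N,
100 Hz), and a forward center-of-mass (COM) position trace (m). All series
are uniformly sampled; after parsing, time is carried as sample index plus
rate.

**Integrity screen.** Trials whose insole and IMU durations disagree by more
than a tolerance (default 0.1 s) indicate a logging fault and are rejected.
The rule needs a tolerance to be operational; 0.1 s (ten samples) separates
real logging faults from rounding of stream lengths.

**Gait events.** Foot contact is defined by total plantar force crossing
50 N. With that floor, the force minima between steps lie entirely in the
sub-threshold swing region, so the reproducible implementation of
minima-based parsing is: heel strike = first sample at/above threshold after
a confirmed off interval, toe-off = start of the next confirmed off
interval. "Confirmed" means at least 0.05 s below threshold (debounce),
which suppresses chatter at the threshold line; leading/trailing partial
contacts are discarded. A stride is the half-open window between consecutive
heel strikes, so strides tile the heel-strike span exactly.

**Stride features.** Per channel: max and min over [hs, next_hs); absolute
impulse ∫|x| dt over the stride; signed stance impulse over [hs, to] and
swing impulse over [to, next_hs]. Integrals use the trapezoidal rule on the
*closed* sample windows, so stance + swing equals the full-stride signed
integral exactly and a constant c over a T-second stride integrates to cT.
The price is that the boundary sample at `next_hs` (shared with the next
stride) participates in the integral; max/min remain half-open. Stance and
swing times derive from the insole and enter the table once, not once per
IMU, to avoid duplicated columns under multi-sensor configurations.

**Decimation.** Lower-rate sensors (50, 25 Hz) are simulated by keeping
every k-th sample with no anti-alias filter, because a sensor natively
configured to a lower rate applies none. Only the IMU is degraded; the
insole and COM streams are lab-grade reference equipment and stay at 100 Hz.
Stride windows live on the insole clock and are mapped to a decimated IMU
clock by time-proportional index rounding (half up).

**Targets.** Per-sample Achilles load is `lever_ratio × force /
body_weight`; the published physics-based insole-to-tendon models are not
reproduced here, so the estimator is an explicitly documented stand-in that
is monotone in plantar force (default lever ratio 1.0) and replaceable; on
synthetic cohorts the generator supplies exact ground truth. Stride peaks
under 0.5 BW are excluded from modeling; the boundary is inclusive (a peak
of exactly 0.5 BW is kept) because the exclusion rule targets values *under*
the threshold. Walking speed is net COM displacement over elapsed time per
trial, broadcast to the trial's strides; the R² of COM position vs time is
reported as a constant-speed check and flags (but does not reject) trials
below 0.98.

## The regression model

Both targets are fitted by LASSO: minimize (1/2n)‖y − β₀ − Zβ‖² + α‖β‖₁,
where Z holds z-scored features (means/SDs computed from the training rows
only; zero-variance features are dropped from the design and reported with
coefficient 0) and the intercept is unpenalized. The penalty α is selected
by inner K-fold CV (default K = 5, seeded) minimizing MAPE — matching
selection to the metric the models are judged by — over a 30-point log grid
spanning [1e−4, 10] times the critical penalty α_max = max|Zᵀ(y − ȳ)|/n.
Ties break toward the larger penalty (sparser model). Each fitted model
selects its penalty independently. Targets must be strictly positive, which
the 0.5 BW filter and speed positivity guarantee upstream.

`StrideLassoModel.fit()` returns a results object carrying coefficients (in
standardized units), the scaler, the selected penalty, the inner-CV MAPE
curve as a diagnostic, a `summary()` table, name-aligned `predict()`, and
JSON persistence. MAPE grades follow the a priori clinical thresholds:
excellent < 10 %, acceptable < 20 %.

## Evaluation protocol

Models are fitted separately per heel-wedge condition (30°, 5°, 0°) and
target. Three paradigms:

- **generalized** — leave-one-subject-out; each subject held out once, the
  per-subject MAPEs aggregated as mean ± SD across subjects (sample SD,
  subjects weighted equally regardless of stride counts);
- **hybridized** — training adds half of the test subject's kept strides to
  the other subjects' data; testing on the remaining half;
- **personalized** — training on that half alone.

The 50/50 split is random at stride level with a fixed seed and *shared*
between hybridized and personalized so their test sets coincide and paradigm
contrasts are paired. Subjects with no kept strides — or too few to support
the inner CV of a personalized fit — are excluded from that paradigm with a
logged warning.

Sensor ablations re-run decimation → segmentation → extraction → evaluation
per configuration; the benchmark grid is boot/acc+gyr/100 Hz (baseline),
boot/acc/100, boot/acc+gyr/50, boot/acc+gyr/25, and boot+contralateral-foot/
acc+gyr/100.

The learning curve subsamples the pooled training rows of each
leave-one-subject-out fold at a given fraction (not whole subjects), repeats
with fresh seeds (default 5) and averages; fraction 1.0 reproduces the
generalized evaluation exactly. Dual-sensor agreement is the signed maximum
over integer lags (bounded at ±1 s, since synchronization error is small and
an unbounded search invites spurious maxima) of the Pearson correlation of
the overlapping segments, in percent.

## The synthetic cohort generator

The generator's defaults are the study conditions: 10 subjects × 3 wedge
conditions × 4 self-selected speeds (pathological 0.6, slow 0.9, medium 1.2,
fast 1.5 m/s nominal) × 7 trials × 7 strides = 5880 strides, a desk-scale
echo of a full in-lab collection of several thousand strides. Body weight is
drawn per subject (700 ± 90 N, truncated).

Ground-truth targets follow a linear-plus-offset structure:

- load per stride: `base(condition) + 0.6·(v − 1) + subject offset +
  N(0, noise_sd)` BW, with `base = 2 − wedge/30` (so 0° > 5° > 30°,
  progressive re-loading), subject offsets N(0, 0.35 BW), stride noise
  0.08 BW; floored at 0.15 BW so every stance stays detectable;
- trial speed `v`: label base + subject offset N(0, 0.04 m/s) + trial jitter
  N(0, 0.03 m/s).

Waveforms are stylized but carry the encodings the models rely on. Stance
force is a smooth, edge-tapered double bump (weight acceptance + push-off)
normalized so its sampled peak equals `load × BW / lever_ratio` exactly;
swing force is zero, guaranteeing 50 N detectability of every stride.
Ground-truth stride boundaries are recorded as the contact's first/last
supra-threshold samples, i.e. the boundaries of the detectable contact. The
boot accelerometer SI channel is gravity plus a heel-strike transient whose
amplitude is linear in speed (2 + 6·v m/s², with multiplicative jitter); the
transient has a smooth 60 ms flat top so its sampled maximum is *identical*
at 100/50/25 Hz — decimation degrades sampling density, not the speed
encoding, which is the premise of the sampling-rate ablation. The gyroscope
ML channel oscillates stance/swing with extrema scaling with cadence;
remaining channels are AR(1) noise. The COM trace is v·t plus a 4 mm
sinusoidal sway (R² > 0.98). A contralateral-foot IMU sees the same pattern
half a cycle out of phase at 0.85 amplitude.

Two design points matter for interpreting results. First, subject-specific
*load* offsets are deliberately invisible to every IMU feature: that is the
mechanism by which generalized load models degrade on unseen subjects while
personalized models absorb the offset into their intercept — the ordering
personalized < hybridized < generalized is therefore a structural property
of the cohort, and the package's evaluation must recover it. Second, walking
speed is encoded directly and almost noiselessly in the kinematic features,
so generalized speed models far outperform generalized load models. Real
gait is messier on both counts: the synthetic MAPEs (≈2 % speed, ≈10–20 %
generalized load) are cleaner than what boot-worn sensors achieve on humans,
so passing tests demonstrate the pipeline's correctness and its qualitative
orderings, not field accuracy.

What the generator does **not** emulate: full 3-D kinematics, pathological
asymmetry beyond a speed/loading shift, the insole's 3-part regional
partition (total force only), soft-tissue artifact, or sensor drift.

## Reproducibility and numerics

One global seed drives named substreams (simulate, split, inner-cv,
learning-curve); each subject draws from its own (seed, index) substream so
subsetting subjects preserves their data. Identical config + seed yields
byte-identical outputs. Coordinate-descent fits cap iterations on the inner
CV path (where near-zero penalties on collinear features converge slowly and
precision there cannot change the selected penalty) and tighten tolerance
for the final refit. Degenerate inputs are defined errors: empty force
traces, non-positive body weight, zero-variance targets, non-positive MAPE
references, windows out of range.

## Problem sizes

Default test and acceptance runs use the 5880-stride cohort above; the
acceptance script's full baseline grid (18 cells, each fitting 10–30 LASSO
models with inner CV) completes in a few minutes on one CPU. Unit tests use
a 120-stride single-condition cohort.

## Known limitations

- The lever-ratio load stand-in reproduces load *scale*, not the regional
  physics of a validated insole-to-tendon model; absolute BW values on real
  insole data should not be read as tendon forces without calibration.
- MAPE-based penalty selection uses a single shared standardization of the
  training rows across inner folds; fold-wise re-standardization would be
  marginally stricter but changes nothing at these sample sizes.
- The hybridized paradigm's gain over generalized is modest by construction
  (a shared linear model cannot carry per-subject intercepts), so its
  position between the other two paradigms is a small-margin effect.
- Stride-level 50/50 splits ignore trial structure; strides of one trial can
  appear on both sides of a personalized split, which slightly flatters
  within-subject accuracy when trial-level autocorrelation exists (the
  generator's stride noise is independent, so not here).
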