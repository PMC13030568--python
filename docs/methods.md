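# Methods

This note documents the models, assumptions and numerical choices behind
`rtfatigue`: what the pipeline computes, what the synthetic cohort generator
does and does not emulate, and therefore what a passing test suite does and
does not demonstrate about recorded data.

## The detection problem

One sample is a 60-second, non-overlapping window of simultaneous gaze and
ECG recording, labelled by the Samn–Perelli 7-point (SP-7) rating the
controller gave at the end of the scenario the window belongs to. The
extreme-group rule maps scores 1–3 to *alert* (negative), 5–7 to *fatigue*
(positive) and excludes the transitional score 4 from model fitting (it
remains in the feature table). The operational constraint shaping the whole
design is severe class imbalance — roughly 17 alert windows per fatigue
window — combined with asymmetric costs: a missed fatigue episode matters
more than a false alarm, so the pipeline consistently prefers sensitivity.

## Signal processing

**Gaze (100 Hz, degrees of visual angle + pupil diameter in mm).**
Zero-pupil runs are partitioned by duration: under 75 ms is treated as a
tracker dropout (x, y and pupil linearly interpolated, nothing counted);
75–500 ms is a blink (gaze interpolated to keep the trajectory continuous,
pupil kept at zero so closure time is preserved for PERCLOS); over 500 ms is
an eye closure (samples invalidated and excluded from event parsing). I-VT
classifies each sample by angular velocity (central difference; one-sided at
the ends): below 30°/s is fixation, at or above it saccade. Blink samples
split fixations (a blink inside a fixation yields two fixation events).
Fixation runs shorter than 100 ms — a common I-VT convention, configurable —
are relabelled saccade. PERCLOS is the fraction of window time with the eye
closed; since wearable trackers report no eyelid aperture, zero-pupil time
stands proxy for the classical 80 %-closure criterion, and this proxy status
is deliberate and documented. PDV is the within-window standard deviation of
pupil diameter over valid open-eye samples.

**Gaze entropies.** The panoramic display is tiled by an M×N grid of areas
of interest (default 4×8 over a 48°×16° three-screen span; both configurable
— no canonical values exist). Stationary gaze entropy is the Shannon entropy
(bits) of the fixation distribution over *non-empty* cells; it is not
normalized by log₂ K. Transition gaze entropy is the conditional entropy of
the AOI-to-AOI transition chain between consecutive fixations,
self-transitions included, with source-cell weights taken from the empirical
transition counts. Both are bounded by log₂ K, which is asserted as a
property test.

**ECG (512 Hz, mV).** Denoising is an 8-level sym8 wavelet decomposition;
all detail coefficients are soft-thresholded at the universal threshold
λ = σ√(2 log N) with σ estimated from the finest detail level
(median absolute deviation / 0.6745 — the standard estimator; the noise
model does not pin one down), and the level-8 approximation is zeroed, which
removes baseline wander below ~1 Hz. QRS detection follows the classic
Pan–Tompkins chain — 5–15 Hz zero-phase band-pass, five-point derivative,
squaring, 150 ms moving-window integration, adaptive dual thresholds with a
200 ms refractory period and a search-back pass at half threshold — with
detected peaks refined to the local maximum of the denoised trace within
±40 ms. Windows whose implied heart rate leaves 40–180 bpm are flagged
implausible and rejected. RR intervals deviating from the local mean (up to
5 nearest accepted neighbours, single pass) by strictly more than 20 % are
removed as ectopic and leave a gap flag; RMSSD never pairs across a gap, so
ectopic removal cannot fabricate variability. Spectral HRV cubic-interpolates
the tachogram to 4 Hz, detrends linearly, applies a Hann taper and
integrates the periodogram over 0.04–0.15 Hz (LF) and 0.15–0.40 Hz (HF).
A 60-s window resolves 0.04 Hz poorly; that limitation is inherent to the
windowing design and accepted. An HF power below 1e-10 ms²·Hz⁻¹ is treated
as numerically zero and LF/HF is emitted as a flagged sentinel (1e6) rather
than dividing interpolation dust by interpolation dust.

## Classifier and imbalance handling

Features are Z-scored with training-partition statistics only (sample SD;
constant features map to 0). SMOTE synthesizes fatigue samples as
`x_new = x_i + δ(x̂_i − x_i)`, δ ~ U[0,1], with x̂_i drawn uniformly from the
k = 5 nearest minority neighbours in *normalized* space (distances are
scale-sensitive); the synthetic count is `round(ratio · N_neg) − N_pos` with
a default target ratio of 0.5, deliberately below parity so the second
mechanism — a positive-class weight `w_pos = N_neg/N_pos`, computed per
training fold on pre-SMOTE labels — stays active. The weight is applied as a
per-instance weight in the binary log-loss, which scales the gradients and
hessians of positive instances exactly as a weighted gradient update would
(verified against a custom-objective implementation in the tests). The
boosted-tree configuration is fixed: learning rate 0.01, 500 estimators,
maximum depth 8, subsample 0.7, colsample_bytree 0.8, single-threaded
histogram construction for bit-level reproducibility from the run seed
(default 42).

**Threshold moving.** The decision threshold maximizes Youden's
J = sensitivity + specificity − 1 over pooled out-of-fold validation scores
(inner 5-fold under the mixed-subject protocol; inner 3-fold within the
training subjects under LOSO — the held-out subject never contributes).
Candidates are all unique scores, the midpoints between them, and {0, 1};
since J changes only at observed scores, ties are broken toward the smallest
*score-valued* candidate, which favours sensitivity.

**Per-subject calibration.** For a new subject, the chronologically first 30
labelled windows form the calibration set; the generic ensemble is frozen
and adaptation (a) continues boosting with 10 shallow (depth-2), strongly
shrunk (η = 0.002) trees fit on the calibration windows, and (b) refits the
threshold on calibration scores. Three robustness rules govern the refit on
such small sets: no refit with fewer than 3 examples of either class; the
midpoint of the J-optimal interval is used rather than its smallest edge
(the edge sits directly on the highest calibration alert score and transfers
poorly); and the generic threshold acts as a lower bound — cross-subject
transfer fails predominantly by specificity collapse, so calibration may
raise the threshold but never undercut the population-validated one. A
single-class or empty calibration set leaves the model unchanged, with a
status note.

## Evaluation protocols

Protocol A: stratified 80:20 split (seed 42 by default), threshold from
inner 5-fold out-of-fold scores, final refit on the full training portion,
report on the untouched test set. Protocol B: leave-one-subject-out with
per-subject metrics and mean ± SD; train/test subject disjointness is
asserted on every fold, and an instrumented test verifies that no test row
ever reaches the normalizer, SMOTE, or weight fitters. Zero-denominator
metrics report 0 with a flag instead of raising, so degenerate LOSO folds do
not abort a sweep. The ablation harness crosses feature modalities (eye 8-D,
ECG 4-D, fused 12-D) with imbalance strategies (none / weight-only /
SMOTE-only / hybrid; "none" means w_pos = 1, no SMOTE, threshold 0.5) under
stratified 5-fold CV. Multi-model comparison uses the classic Friedman
chi-square on within-block ranks (average ranks on ties) with Nemenyi
critical differences at α = 0.05.

## The synthetic cohort

No recordings of this kind are public, so the generator is the package's
test bed. What it emulates:

- **A severity continuum.** Each scenario draws an SP-7 rating from the
  reference per-score window distribution (≈77 % scores 1–3, 18.5 % score 4,
  4.5 % scores 5–7, hence the ≈17:1 binary imbalance), and its physiology is
  the field-wise linear interpolation between an alert preset and a fatigue
  preset at severity (SP-7 − 1)/6. Ratings adjacent across the extreme-group
  boundary (3 vs 5) therefore overlap physiologically — this is what makes
  the binary problem non-trivial and reproduces the monotone PERCLOS↔SP-7
  relation used for label validation.
- **Presets** (alert → fatigue): mean RR 750 → 820 ms, RMSSD target
  25 → 38 ms, LF/HF tone ratio ≈4.3 → ≈0.47 (LF tone at 0.10 Hz, HF at
  0.25 Hz — the band centres — so the generator-true ratio is the closed
  form (lf_amp/hf_amp)²), blink rate 10 → 16 /min, blink duration
  150 → 240 ms, long closures 0.4 → 3.2 /min, fixation duration
  240 → 310 ms, AOI-chain mixing 0.75 → 0.55, pupil 3.6 → 3.4 mm with SD
  0.15 → 0.22 mm. No published effect sizes exist for this population; the
  presets are chosen for physiological plausibility and separability, were
  calibrated once so the default cohort sits between chance and ceiling, and
  are then frozen.
- **Subjects.** Multiplicative log-normal baselines (scale parameter 0.30,
  damped per parameter) on autonomic set-points (mean RR at half scale,
  RMSSD/SDNN at full scale, LF/HF amplitudes at 0.7), pupil size and
  variability, fixation habits, and blink/closure habits (0.3–0.5). This
  between-subject spread on the signal-carrying features is what creates the
  cross-subject generalization gap the LOSO protocol probes; resting HRV and
  blink behaviour genuinely vary this much across people.
- **Signals.** The tachogram is mean RR + two sinusoidal tones + white noise
  (noise SD = RMSSD target/√2, so white noise alone realizes the target);
  the ECG is a Gaussian-kernel PQRST template at each beat time plus 0.2 Hz
  baseline wander, 50 Hz powerline interference and white noise; gaze is a
  fixation/saccade state machine over a Markov chain of AOI cells
  (uniform-mixed by the concentration parameter; concentration 1 gives the
  maximal-entropy uniform chain), raised-cosine ballistic saccades with peak
  velocities far above the I-VT threshold, Poisson blinks and closures, and
  an AR(1) pupil.

What it does **not** emulate: realistic 12-lead ECG morphology or
arrhythmias; motion and electrode artifacts beyond stationary noise;
within-scenario fatigue drift (severity is constant within a scenario);
head-pose and illumination effects on the tracker; task-driven gaze
semantics (traffic events); and correlations between modalities beyond the
shared severity. Consequently, passing tests demonstrate that the pipeline
recovers known ground truth and reproduces the qualitative orderings —
hybrid imbalance handling raises sensitivity, fusion outperforms single
modalities, LOSO underperforms mixed-subject evaluation, calibration helps —
but the *magnitudes* (e.g., a ~5-point LOSO gap here versus the much larger
drops reported for real cohorts) say nothing quantitative about recorded
data.

## Problem sizes and reproducibility

The default `CohortConfig` mirrors the target study design (36 subjects ×
10 scenarios × 10 min ≈ 3,450 windows). The test suite and the acceptance
script run `CohortConfig.compact()` — 12 subjects × 12 scenarios × 6 min =
864 windows at the same prevalences (≈18.5:1 labelled imbalance, ~36 fatigue
windows) — a size at which signal generation, feature extraction, LOSO,
calibration and the ablation grid complete in minutes on one CPU while
keeping the directional comparisons stable across seeds. Detector-quality
checks use 20 independent 60-s records. All stochastic stages consume a
single run seed; identical seeds reproduce cohorts, splits and models
bit-for-bit (single-threaded training).

## Known limitations

- A 60-s window cannot resolve the lower LF band edge; LF/HF at this window
  length is noisy by construction.
- The PERCLOS proxy (zero-pupil time) conflates blinks, closures and any
  unmodelled tracker loss.
- Calibration can only act when the first 30 windows contain both classes;
  at 17:1 imbalance most calibration sets are single-class and leave the
  generic model unchanged, so cohort-mean calibration gains are small even
  when individual-subject gains are large.
- The severity continuum is linear in every parameter; real fatigue dynamics
  are certainly not, and scenario-level ratings blur within-scenario change.
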