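# rtfatigue

Multimodal fatigue detection for remote tower (rTWR) air traffic controllers.

Remote tower operations replace the out-the-window view with prolonged
screen-based surveillance, and the cognitive fatigue this induces is a
safety-critical, *rare-event* detection problem: alert minutes outnumber
fatigued minutes by roughly 17:1, and a missed fatigue episode costs far more
than a false alarm. `rtfatigue` implements an end-to-end pipeline that turns
raw wearable eye-tracking (100 Hz) and single-lead ECG (512 Hz) streams into
60-second window-level predictions of a binary alert/fatigue state:

1. **Ocular pipeline** — blink repair (zero-pupil runs: < 75 ms dropouts
   interpolated, 75–500 ms blinks, > 500 ms closures), I-VT fixation/saccade
   parsing (30°/s angular-velocity threshold), and eight oculometric features:
   PERCLOS, blink frequency BF, mean blink duration MBD, mean fixation
   duration MFD, fixation frequency FF, pupil-diameter variability PDV, and
   two scanpath entropies over an M×N grid of areas of interest —
   stationary gaze entropy
   `H_SGE = −Σᵢ pᵢ log₂ pᵢ`
   and transition gaze entropy
   `H_TGE = −Σᵢ pᵢ Σⱼ pᵢⱼ log₂ pᵢⱼ`.
2. **Cardiac pipeline** — sym8 8-level wavelet denoising with soft
   thresholding at the universal threshold `λ = σ√(2 log N)`, Pan–Tompkins
   QRS detection (band-pass → derivative → squaring → 150 ms moving-window
   integration → adaptive dual thresholds), ±20 % ectopic-interval rejection,
   and four HRV features: MeanRR, SDNN, RMSSD and the LF/HF spectral ratio
   (LF 0.04–0.15 Hz, HF 0.15–0.40 Hz).
3. **Fusion and labeling** — early fusion into a fixed-order 12-D vector;
   extreme-group labels from post-scenario Samn–Perelli (SP-7) ratings
   (1–3 alert, 5–7 fatigue, 4 excluded); Spearman/t-test validation of the
   labels against PERCLOS.
4. **Cost-sensitive model** — training-set-only Z-score normalization, SMOTE
   oversampling of the fatigue minority (k = 5), an XGBoost classifier
   (η = 0.01, 500 trees, depth 8, subsample 0.7, colsample 0.8) with the
   positive class weighted by `w_pos = N_neg/N_pos` per training fold, and
   Youden-J threshold moving (`J = sensitivity + specificity − 1`) in place
   of the 0.5 cutoff.
5. **Evaluation** — mixed-subject stratified 80:20 (Protocol A),
   leave-one-subject-out (Protocol B), a 30-window per-subject cold-start
   calibration experiment, a modality × imbalance-strategy ablation grid,
   and Friedman + Nemenyi multi-model comparison.

No recordings of this kind are publicly available, so the package ships a
first-class **synthetic cohort generator** (`rtfatigue.synthetic`) with known
ground truth: scenario physiology sits on an alert→fatigue severity continuum
indexed by the SP-7 rating, subjects carry multiplicative physiological
baselines, and the emitted rating distribution reproduces the ≈17:1 window
imbalance. Every detector and every claim in the test suite is checked
against this generator's ground truth.

## Worked example

```python
from rtfatigue import synthetic, dataset, evaluation

# a desk-scale cohort: 12 subjects x 12 scenarios x 6 min, seed 1
cohort = synthetic.gen_cohort(synthetic.CohortConfig.compact(seed=1))
features, rejected = dataset.build_feature_table(
    cohort.gaze, cohort.ecg, cohort.session, cohort.grid
)
print(len(features), dataset.validate_labels(features))

rep = evaluation.run_protocol_a(features, seed=1)
print({k: round(v, 3) for k, v in rep.overall.items() if isinstance(v, float)})

loso = evaluation.run_protocol_loso(features, seed=1)
print(round(loso.mean["accuracy"], 3))
```

prints (exactly these numbers for seed 1):

```
864 {'status': 'ok', 'spearman_r': 0.527, 'spearman_p': 2.0e-51,
     't_stat': 12.278, 't_p': 1.6e-31}
{'accuracy': 0.943, 'precision': 0.467, 'sensitivity': 1.0,
 'specificity': 0.94, 'f1': 0.636, 'auc': 0.999, 'threshold': 0.142}
0.887
```

Reading: 864 windows were extracted; per-window SP-7 ratings correlate with
PERCLOS (ρ = 0.53) and the fatigue group closes its eyes significantly more
(t = 12.3), validating the labels. Under mixed-subject evaluation the model
catches every fatigue window (sensitivity 1.0) at 94 % specificity — the
deliberately sensitivity-first operating point produced by threshold moving.
Under leave-one-subject-out the mean accuracy drops to 88.7 %: the
cross-subject generalization gap that per-subject calibration then narrows.

The same pipeline is scriptable from the shell:

```bash
rtfatigue simulate --compact --seed 1 --out cohort/
rtfatigue extract-features --data cohort/ --out features.csv
rtfatigue train --features features.csv --out model.json
rtfatigue evaluate --features features.csv
rtfatigue loso --features features.csv
rtfatigue ablate --features features.csv
```

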