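# slowwave

A tested pipeline for classifying gastric myoelectric (slow-wave) recordings
between baseline and feeding states, driven by a seeded synthetic ferret
slow-wave signal generator so every stage runs with no external data.

The pipeline covers:

- **`slowwave.synth`** — synthetic multichannel serosal recordings: a shared
  amplitude-modulated slow wave (default 0.15 Hz) with per-channel phase/gain,
  a condition-dependent tachygastric component (feeding shifts power toward
  0.45 Hz), baseline drift, broadband noise, amplifier-saturation dropouts
  (clipped to ±187.5 mV) and >2 mV movement transients; CSV export/import.
- **`slowwave.preprocess`** — the five-stage chain: (1) decimation to 200 Hz
  with an anti-aliasing filter, (2) zeroing of saturated samples, (3)
  zero-phase Butterworth band-pass 0.05–0.7 Hz, (4) linear interpolation of
  >2 mV artifact runs, (5) per-channel QC against three inclusion criteria
  (<20% dropped, <20% interpolated, band power above threshold), with a
  Table-style QC report and study-wide channel exclusion.
- **`slowwave.windows`** — segmentation into labeled 1-minute windows
  (12,000 samples at 200 Hz) and stratified (optionally subject-grouped)
  3-fold cross-validation plans.
- **`slowwave.spectral`** — Welch PSD (2^14 FFT points), 10 equal-width
  band-power features over 0.05–0.7 Hz per retained channel (30 features for
  3 channels), training-fold z-scoring, and forward/backward sequential
  feature selection minimizing Monte-Carlo-averaged CV misclassification.
- **`slowwave.shallow`** — linear/RBF SVM, LDA, QDA, logistic regression and
  random forest with a common posterior-score contract in [0, 1] (margin
  classifiers get a strictly monotone Platt map fitted on training folds).
- **`slowwave.resnet1d`** — a 1D residual CNN: five stride-2 blocks
  (kernel 121, channels 6/12/24/48/96, batch-norm, kernel-1 stride-2 skip),
  a kernel-1 single-channel head, flatten (12,000 → 375 features), fully
  connected layer and sigmoid; BCE loss, AdamW, dropout, early stopping
  (patience 50, max 200 epochs, batch 20, lr 0.001). Implemented in pure
  NumPy with FFT-domain convolutions and manual backprop, so no deep-learning
  framework is required; it trains in minutes on one CPU core.
- **`slowwave.evaluate`** — ROC/AUC (trapezoid, midpoint tie convention),
  accuracy/sensitivity/specificity at threshold 0.5, repeated k-fold CV with
  per-subject breakdowns, and CSV/PNG report rendering.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (structural targets,
the channel-quality worked example, oracle-equivalence properties,
permutation-null behavior, and signal-recovery design targets on synthetic
data). The full suite runs in a couple of minutes on one core.

## CLI

```bash
slowwave simulate  --out-dir raw --seed 1            # synthetic study CSVs
slowwave preprocess --in raw --out clean --qc-report qc.csv
slowwave segment   --in clean --out wins
slowwave featurize --in wins --out features.csv
slowwave select    --features features.csv --classifier lda --direction forward --mc 100 --out mask.csv
slowwave train-shallow --features features.csv --classifier svm_rbf --repeats 10 --out report/
slowwave train-cnn --windows wins --config cfg.yaml --repeats 1 --out report/
```

A YAML config can override any generator/preprocessing/training parameter;
see `slowwave/config.py` for the section layout.

## Notes

- Scores use the convention 0 = baseline, 1 = feeding; sensitivity is the
  feeding true-positive rate, specificity the baseline true-negative rate;
  predictions use `score >= 0.5` (boundary inclusive).
- The QC power criterion's units are ambiguous in the source protocol; the
  threshold and signal scaling are config parameters (`qc_min_power`,
  `qc_power_scale`), defaulting to the documented worked-example scale.
- All randomness flows from explicit seeds; identical seeds reproduce
  recordings, fold plans, training runs and reports bit-for-bit.
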