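# emophysio

A two-branch pipeline for emotion-state analysis from wearable physiological
recordings:

* **EDA branch** — skin-conductance level (SCL) pre-processing (cubic-spline
  gap filling, zero flooring) and emotional-stimulus **trigger-mark
  detection** from peaks of the smoothed second derivative.
* **ECG branch** — down-sampling (1024 → 256 Hz), trigger-based session
  segmentation, sliding min/max window outlier removal, Pan–Tompkins-style
  R-peak detection, RR cleaning (generalized extreme Studentized deviate test
  + modified Akima interpolation), and **eight HRV features** (RMSSD, SDNN,
  mean RR, HR, and Lomb–Scargle HF/LF/VLF band powers + HF/LF ratio).
* **Classifiers** — a Gaussian-kernel SVM (kernel scale 6.385, box constraint
  956.32, optional Bayesian hyperparameter search) separating *emotion* vs.
  *rest* segments, and a small CNN trained with SGD-momentum and
  class-weighted cross-entropy classifying *low/mid/high* arousal strength
  from Morlet CWT scalogram images.
* **Synthetic data** — a protocol-structured session generator (Gaussian
  PQRST beat trains with stage-dependent HRV, tonic+phasic SCL, NaN gaps,
  negative dips, spike bursts) standing in for the unavailable study
  recordings; ground truth is stored alongside every session.
* **Evaluation** — arousal-scale conversion, stratified splits, 5-fold Monte
  Carlo cross-validation, confusion-matrix metrics (precision, recall,
  F-beta, TP accuracy), and dataset distribution tables.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance-criteria suite (dataset
bookkeeping worked examples, brute-force formula oracles, bit-exact
outlier-removal instances, trigger-detection recall/RMSE properties,
end-to-end parameter recovery, and CWT ridge localization).

## CLI

```bash
emophysio simulate --out cohort/ --subjects 4 --seed 1   # synthetic cohort (HDF5)
emophysio preprocess-eda cohort/S00.h5 --out clean.csv
emophysio triggers cohort/S00.h5 --out triggers.csv
emophysio preprocess-ecg cohort/S00.h5 --out rr/
emophysio features cohort/ --out features.csv
emophysio scalograms cohort/S00.h5 --out imgs/
emophysio train --model state --features features.csv --out state.pkl
emophysio evaluate cohort/ --out report.json
emophysio report report.json
```

Sessions are written as HDF5 (`/ecg`, `/scl` datasets with `fs`/`units`
attributes, `/annotations` table, `/truth` group) with an optional plain-CSV
dialect (`time_s,value` per channel plus an annotations CSV).

## Layout

```
src/emophysio/
  synthetic.py     session/cohort generator
  eda.py           SCL cleaning + trigger detection
  ecg.py           down-sampling, segmentation, outlier removal, R peaks, RR cleaning
  hrv.py           8 HRV features, Lomb–Scargle bands, min–max scaling
  scalogram.py     Morlet CWT scalograms and image rendering
  classifiers/     SVM state model, numpy CNN arousal model, weighted CE loss
  evaluation.py    metrics, CV, splits, dataset tables, orchestration
  io.py            HDF5/CSV dialects
  cli.py           command-line interface
```
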