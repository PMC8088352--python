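# neurospect

Spectral-moment EEG features and three-class diagnostic classification
(MCI / AD / HC), driven by a synthetic EEG cohort generator.

The pipeline has five stages:

1. **simulate** — generate a labelled three-class cohort of multichannel EEG
   records (19-channel 10-20 montage, 300 s at 256 Hz by default).  Each
   class has a distinct relative band-power profile (slow-wave excess for
   AD, alpha dominance for controls, MCI in between), built from
   band-limited Gaussian noise plus a 1/f background.
2. **preprocess** — integer-factor decimation to 256 Hz (zero-phase
   anti-alias filtering) and extraction of the 60–240 s window.
3. **extract** — seven time-domain power-spectrum descriptors per channel
   (log spectral moments, sparseness, irregularity factor, coefficient of
   variation, Teager energy), averaged across channels into one 7-vector
   per subject.
4. **train** — stratified 80/20 split, then KNN / RBF-SVM / LDA
   (scikit-learn) and a small deterministic numpy CNN
   (conv → batch-norm → ReLU → max-pool → conv → batch-norm → ReLU →
   dense → dropout → dense → softmax, Adam).
5. **evaluate** — 3×3 confusion matrix, per-class sensitivity / precision /
   miss rate, overall accuracy, one-vs-rest ROC curves with trapezoid AUC,
   and a combined summary table.

Everything is reproducible from one global seed: per-subject and per-stage
seeds are derived with a splitmix-style mixer, so a re-run regenerates every
output byte for byte.

## CLI

```sh
# generate a cohort (CSV or EDF signals + manifest.csv)
neurospect simulate --n-per-class 64 --fs 256 --duration 300 --seed 1 \
    --out cohort/ --format csv

# resample + window every record in a cohort
neurospect preprocess --in cohort/ --out windowed/ --start 60 --end 240 --fs 256

# per-subject features
neurospect extract --in windowed/ --out features.csv --lambda 0.1

# train one classifier on the 80/20 split, then evaluate it
neurospect train --features features.csv --model cnn --seed 1 --out model/
neurospect evaluate --model model/ --features features.csv --out report.json

# or run the whole chain from a config
neurospect run-all --seed 1 --out results/run1/
```

`run-all` writes `features.csv`, one `report_<model>.json` and
`roc_<model>.csv` per classifier, the CNN training curve, and a combined
`summary.csv` (sensitivity / precision / AUC / accuracy per model).

## Layout

- `src/neurospect/synthetic.py` — cohort generator and class profiles
- `src/neurospect/preprocess.py` — decimation and windowing
- `src/neurospect/tdpsd.py` — the seven descriptors and feature tables
- `src/neurospect/classifiers.py` (+ `_cnn.py`) — models and split logic
- `src/neurospect/evaluation.py` — confusion matrix, ROC/AUC, report
- `src/neurospect/io.py`, `cli.py`, `pipeline.py` — formats, config, CLI,
  end-to-end run (`_edf.py` is a minimal EDF writer/reader)
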