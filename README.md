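# dte — confidence-calibrated activity recognition with deep time ensembles

Wearable-sensor human activity recognition (HAR) models are usually
trained for accuracy alone, and their softmax outputs are overconfident:
a prediction made with confidence 0.99 is right far less than 99% of the
time. For downstream use (health monitoring, geriatric care, any
safety-relevant pipeline) the probability itself matters.

This package implements **deep time ensembles (DTE)**: train one
probabilistic sequence classifier per window size in a descending set
`w1 > w2 > … > wN`, and at inference slide each member's window inside the
outer `w1`-sized test window, average its softmax over the sub-windows,
then average the members uniformly,

    p(y|x) = (1/N) Σ_j  mean_subwindows softmax_j(·),

which softens overconfident single-model softmax output while preserving
(usually improving) classification. Calibration is quantified by the
expected calibration error over M equal-width confidence bins,

    ECE = Σ_m (n_m/N) |acc(B_m) − conf(B_m)|,    M = 10,

together with reliability diagrams, per-bin (binwise) ECE, and a
temperature-scaling comparison (`softmax(z/T)`, T fitted on a validation
split from T₀ = 1.5).

The package contains:

* `dte.synthgen` — a synthetic multi-subject wearable-signal generator
  (strongly periodic / weakly periodic / aperiodic activities, imbalanced
  classes, subject-disjoint splits), so everything runs without downloads;
* `dte.windowing` — temporal-matrix extraction (sliding windows, majority
  labels, window-size sets built by uniform stepping around a centre);
* `dte.learners` — small conv / recurrent / conv-recurrent classifiers on
  a hand-written numpy layer library (gradient-checked), trained with
  cross-entropy + Adam;
* `dte.ensemble` — `DeepTimeEnsemble` / `StandardEnsemble` model classes
  whose `fit()` returns an `EnsembleResults` object (statsmodels-style);
* `dte.calibration` — ECE, reliability data, temperature scaling;
* `dte.cli` — `dte simulate | run | report | ece`.

## Worked example

```python
from dte.experiment import ExperimentConfig, get_splits, run_repeat

config = ExperimentConfig()          # the reference synthetic study
train, val, test = get_splits(config, seed=3)
run = run_repeat(train, val, test, config, seed=3)
for name, m in run["metrics"].items():
    print(f"{name:>18} acc={m['accuracy']:.3f} ece={m['ece']:.4f}")
```

prints (one master seed; ~1 minute on one CPU):

```
               dte acc=0.827 ece=0.0630
          baseline acc=0.797 ece=0.1702
       baseline_ts acc=0.797 ece=0.0423
            dte_ts acc=0.827 ece=0.0285
 standard_ensemble acc=0.797 ece=0.1286
```

Reading: the single-window baseline (largest window, 4 s) reaches accuracy
0.797 on the two held-out subjects but carries an ECE of 0.170 — its
confidences overshoot its accuracy badly. The five-size window ensemble
(`dte`, windows 2–4 s) is both more accurate (0.827) and far better
calibrated (ECE 0.063, a 63% reduction) with no post-processing, while the
same-window "standard ensemble" (five members differing only in
initialization) helps calibration much less on this seed (0.129) and gains
no accuracy. Temperature scaling sharpens the comparison: it repairs much
of the baseline's miscalibration (0.042) and combines well with the
ensemble (0.029), but requires a representative validation split.

The same workflow from the shell:

```bash
dte simulate -c config.yaml --out data/
dte run      -c config.yaml --out results/
dte report   results/                 # reliability diagrams, binwise ECE
dte ece      results/run_0/dte.csv    # standalone metric
```

`EnsembleResults.summary()` prints the member table (window sizes, sample
counts, training-window counts, architecture); see `docs/methods.md` for
the model, conventions and study conditions.

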