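# Methods

## Problem and model

Human activity recognition (HAR) from wearable sensors is multivariate
time-series classification: a recording `s_1..s_n` with per-sample labels
`l_1..l_n` is cut into fixed-length windows, and a neural classifier maps
each window to a softmax distribution over K activities. Classifiers
trained this way are typically *overconfident*: the maximum softmax
probability exceeds the empirical probability of being correct, which makes
the probabilistic output unreliable downstream.

The package implements a *deep time ensemble* (DTE). Instead of one model
at one window size it trains N models, one per window size in a descending
set `w1 > w2 > ... > wN`:

* **Training.** For each `w_i`, slide a window of `round(w_i * rate)`
  samples over every recording with a chosen step, label each window with
  its most frequent per-sample label, and fit one classifier on the
  resulting temporal matrix with cross-entropy.
* **Inference.** A test example is a window framed at the largest size
  `w1`. Member j slides its own window `w_j` inside that outer window,
  averages its softmax over the sub-windows, and the member distributions
  are combined by an unweighted mean: `p(y|x) = (1/N) Σ_j y_j`.

Two mechanisms drive calibration: members trained on different temporal
scales disagree where the evidence is ambiguous, and the double averaging
(sub-windows within a member, then across members) can only soften the
combined maximum probability — the combined max never exceeds the largest
member max. The predicted label is the argmax of the combined distribution,
so classification is preserved while confidence is tempered.

## Calibration measurement

Confidence of an example is the maximum of its predicted distribution.
With M equal-width bins `B_m = ((m-1)/M, m/M]` (right-inclusive, bin 1
closed at 0, M = 10 by default):

    acc(B_m)  = mean correctness of examples in the bin
    conf(B_m) = mean confidence of examples in the bin
    ECE       = Σ_m (n_m / N) |acc(B_m) − conf(B_m)|

Empty bins carry zero weight in ECE and are reported as empty (NaN), not
as a zero gap. The per-bin gaps themselves (binwise ECE) and the per-bin
table behind a reliability diagram are exposed directly. Argmax ties break
to the smallest class index everywhere (windowing majority labels,
prediction, binning), so the pipeline is deterministic and seed-free at
inference.

Temperature scaling is the post-hoc comparison: a scalar T > 0 fitted on a
validation split by minimising the NLL of `softmax(z / T)` (bounded 1-D
L-BFGS-B on T ∈ [0.05, 100], started from T = 1.5, tolerance ~1e-12 on the
objective). T is applied to pre-softmax scores, the standard formulation;
the averaged ensemble output has no native scores, so `log(p + 1e-12)` is
used as a surrogate (T = 1 then reproduces the input probabilities to the
epsilon floor). If the validation split lacks a class the fit warns rather
than fails, since an incomplete validation set can push T below 1.

## Learners

No deep-learning framework is assumed: the three reference architectures
are implemented on a small numpy layer library (valid 1-D convolution via
im2col, tanh recurrence with exact backpropagation through time, dense
output, ReLU, global average pooling) trained with Adam and verified by
finite-difference gradient checks.

* `conv` — two valid convolutions (12 filters, kernel 7) + ReLU, global
  average pooling, linear output. Default; fastest and adequate for the
  synthetic signals.
* `recurrent` — two stacked tanh recurrent layers (24 units),
  classification from the final hidden state.
* `conv_recurrent` — one strided convolution feeding one recurrent layer.

Inputs are standardized per channel with training-set statistics stored on
the fitted learner. Training is fixed-epoch (35 by default, batch 32,
learning rate 1e-2) with no early stopping: a simpler reproducibility
contract. The default epoch count trains the small networks to
convergence on the reference study — the regime the method addresses is a
*converged* classifier whose held-out confidence overshoots its accuracy,
and an under-trained baseline never reaches it. All initialization and shuffling derive from the learner seed;
member i of an ensemble fitted with master seed s uses seed s + i, so a
one-member ensemble is bit-identical to the bare learner (the reduction
law tested in the suite). Bit reproducibility is guaranteed within one
runtime environment, not across BLAS implementations.

## Windowing conventions

* "Overlap" is a slide increment: the extraction step is given in samples,
  seconds, or as a fractional overlap o ∈ [0, 1) mapped to
  `step = max(1, round(w(1−o)))`.
* Coordinates are 0-based half-open `[start, start+w)`; trailing partial
  windows are dropped (`count = floor((n−w)/step) + 1`, 0 when the window
  does not fit).
* Windows never cross recording (subject/session) boundaries, preventing
  subject leakage.
* Inference sub-windows default to non-overlapping (`stride = w_j`),
  configurable, and the outer window's majority label at `w1` is the
  evaluation ground truth.

## Synthetic data

The generator emulates the statistical structure the method assumes rather
than any particular benchmark: several activity classes with heterogeneous
periodicity, imbalanced class frequencies, multiple subjects, subject-
disjoint splits, fixed sampling rate. Three regimes:

* strong periodicity — a harmonic stack of a base period plus white noise
  (locomotion-like);
* weak periodicity — the same stack with per-cycle Gaussian period jitter,
  which broadens the spectral peak (semi-rhythmic chores);
* none — a constant offset plus AR(1) (low-pass) noise (quasi-static
  tasks).

Channels share the waveform with an independent random phase shift and
independent noise per channel. The default six-class set (two strong, two
weak, two aperiodic; periods 0.55–1.5 s; amplitudes 0.2–1.6; class weights
0.26…0.11) was chosen once as a plausible daily-life mixture at 20 Hz —
periods resolvable at that rate, noise high enough that held-out accuracy
stays below ceiling. Per-subject multiplicative amplitude (sd 0.25) and
period (sd 0.10) factors give subjects visibly individual signal scales
and cadences, as real wearers have. This between-subject variation is
load-bearing: it opens a genuine generalisation gap on subject-held-out
evaluation, which is what makes a converged single-window baseline
overconfident (mean confidence well above held-out accuracy) — the
documented phenomenon the calibration comparison acts on. With nearly
identical subjects the baseline is already almost calibrated and
ensemble softening would only push it below its accuracy.

What the generator does **not** emulate: biomechanics, gravity/orientation
effects, sensor drift, label noise, transitions blending two activities
within a segment. Passing the directional study therefore shows that the
ensembling-and-averaging mechanism calibrates and classifies as intended on
data with the assumed structure — not that any particular accuracy carries
over to a real deployment.

## Reference study conditions

The packaged study (used by `scripts/acceptance.py` and the acceptance
tests) runs at desk scale: 10 subjects (6 train / 2 validation / 2 test),
24 segments of 10 s per subject at 20 Hz with 3 channels; window set
{2, 2.5, 3, 3.5, 4} s built by uniform 0.5 s stepping around a 3 s centre
(5 sizes); training step 1 s, test step 0.5 s (~1,400 training windows per
size, ~950 test windows); the `conv` learner at 35 epochs; M = 10 bins;
10 repetitions with distinct master seeds, metrics reported as means. One
repetition trains 5 ensemble members plus 5 standard-ensemble members in
about a minute on one CPU.

## Design choices that were genuinely open

* **Baseline identity.** The single-model baseline is the learner trained
  at the largest window `w1`, so baseline and ensemble score the exact same
  test windows and labels; by the reduction law it equals the ensemble's
  first member and is reused as such.
* **Inner stride.** Non-overlapping sub-windows by default; denser strides
  are configurable but add inference cost with little change in the
  averaged output on the synthetic signals.
* **Ensemble temperature.** Fitted on surrogate log-probability scores;
  an alternative (per-member temperatures before averaging) is out of
  scope.
* **Standard-ensemble seeds.** Member i uses master seed + i, identical to
  the window-ensemble convention, so the two ensembles share their first
  member when the fixed window equals `w1` — deliberate, making the
  comparison initialization-matched.

## Known limitations

* The recurrent learner's BPTT is O(T) per window in Python-level loops;
  long windows (> a few hundred samples) train slowly.
* ECE with M = 10 on fewer than ~500 test examples is noisy; the study
  sizes were chosen so each run yields ~950 test windows.
* The AR(1) aperiodic regime is stationary; truly non-stationary activities
  (e.g. a subject pausing) are not modelled.
* Temperature fitting assumes the validation split is representative; with
  subject-disjoint splits and few subjects the fitted T varies noticeably
  between seeds.
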