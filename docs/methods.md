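# Methods

## Problem setting

An electronic nose records, per trial, the rising voltage response of S
metal-oxide gas sensors sampled at 1 Hz over an 80 s exposure. Concatenating
the S traces gives one feature vector of length n = 80·S (240 features for 3
sensors, 400 for 5). With six beverage classes and only 12 trials per class
(7 for training, 5 held out), classifiers — especially neural networks — are
data-starved: accuracy is mediocre and varies strongly between independent
trainings. The package implements feature-space data augmentation to
mitigate this, and the harness that measures whether it does.

## Augmentation methods

All methods take the training pool only, emit exactly the requested number
of synthetic trials, preserve the parent's class label, and never mutate the
originals.

**Interpolation–extrapolation (the core method).** A synthetic vector is

    X_N = X_i + α (X_j − X_i),    α ~ Uniform(C1, C2)

where the anchor X_i is drawn uniformly over the training pool and the
partner X_j uniformly over the anchor's k nearest same-class neighbours
(Euclidean distance on raw features, ties broken toward the lower index).
With C1 < 0 or C2 > 1 the synthetic point lies beyond the segment joining
the parents — extrapolation — which injects more variability than pure
interpolation while the kNN restriction keeps generation local to the class
manifold. Defaults: k = 3, (C1, C2) = (−2, 3). The interval can be set by a
single half-width CV centred at 0.5 (C1 = 0.5 − CV, C2 = 0.5 + CV);
CV = 0.5 recovers pure interpolation, CV = 2.5 the default interval.

A note on the anchor: the method description draws X_i "over the original
dataset" while the generating equation requires same-class parents; we draw
the anchor over the whole pool and restrict only the partner to the
anchor's class, which satisfies both statements.

**SMOTE.** The special case (C1, C2) = (0, 1). It shares the sampler with
the method above, so at unit bounds and equal RNG state the two are
bit-identical (features, labels, trial ids). Classic SMOTE targets the
minority class; here all classes are balanced and every class is
oversampled with same-class neighbours, which keeps the baseline exactly
comparable to the proposed method.

**Gaussian noise.** X_G = X_i + ε with ε i.i.d. N(0, σ²) per component,
σ = 0.05 V by default; the parent is drawn uniformly.

**Signal stretching.** The printed formula for the kept prefix length,
m = n(1+α), contradicts its own description of m as "a reduced number of
first elements" whenever α > 0. The default implementation uses the reduced
prefix: m = round(n / (1+α)) samples are kept and linearly resampled onto n
equally spaced positions, producing a slowed copy of the early response
(α = 0.1, n = 80 gives m = 73). The literal reading is available behind the
`eq5_literal` flag (upsample to m = round(n(1+α)) points, keep the first
n); both readings slow the signal by the factor (1+α), approaching each
other from opposite directions. Stretching is applied per sensor segment —
a stretch across segment boundaries would mix independent channels.
The combined noise+stretch method draws T parents and emits one noisy and
one stretched trial per parent (2T total).

## Classifiers

* **ANN-nl-nu** (`MLPClassifier`): nl hidden layers of nu units, tanh
  activations, softmax outputs, cross-entropy loss, Adam. Early stopping
  monitors an internal 15% validation split of the (augmented) training
  pool; patience is 40 non-improving epochs with a cap of 800. The long
  patience matters: with 42-sample pools the default (10) stops the net
  after ~20 epochs, before it has learned anything. Prediction is the
  probability argmax; ties resolve to the lowest class index.
* **MSVM** (`SVC`, linear kernel, one-vs-one voting): deterministic —
  refitting on identical data gives the identical model, so its
  repeat-to-repeat accuracy SD is exactly zero.
* **RF** (`RandomForestClassifier`): 100 trees by default, Gini splits,
  bootstrap sampling; seed-dependent.
* **PCA-nv-MSVM**: PCA fitted on the training pool only (training-mean
  centring, no whitening), nv retained components, then the linear MSVM in
  the reduced space. Test data are projected with the training map, never
  refitted.

No feature scaling is applied by default (an optional standardization flag
exists); the raw voltages are already on a common scale.

## Evaluation protocol

The dataset is split once per experiment: a seeded stratified draw of
7 train + 5 test per class. The test set is fixed across every condition,
classifier and repeat of that experiment; it is never augmented and never
supplies augmentation parents — a leakage guard compares trial-id sets on
every run and raises on overlap.

Each (classifier, augmentation) condition is trained 10 times. Stochastic
classifiers (ANN, RF) get a fresh synthetic draw per repeat from a
dedicated RNG substream, so the reported SD reflects training and
augmentation randomness together; a flag can freeze one pool instead.
Deterministic classifiers (MSVM, PCA-MSVM) always see one frozen pool —
repeated trainings are then genuinely identical, which is what their zero
SD means. Accuracy is percent correct on the test set, reported with the
sample SD (ddof = 1) over repeats; when all repeats coincide the SD is
reported as exactly 0, and a single repeat reports SD 0 with a degenerate
flag. Table means are rounded to 2 decimals; raw per-repeat values are
retained.

The CV sweep evaluates a grid of interval half-widths in [0.02, 4] with 500
synthetic trials per cell, and smooths the mean-accuracy series with a
forward moving average over each value and its 10 successors (window 11,
truncated to the available suffix at the tail). A master seed spawns
labelled substreams (split / augment×repeat / train×repeat), so any cell is
re-runnable in isolation and full runs are bit-reproducible.

## Synthetic trial generator

Real metal-oxide responses rise and saturate; the generator uses a
saturating exponential per sensor:

    v(t) = B_s + A_cs (1 + a)(1 − exp(−t / (τ_cs (1 + b)))) + e(t)

with per-trial relative jitters a ~ N(0, sd_amp²), b ~ N(0, sd_tau²) and
additive noise e ~ N(0, sd_noise²). Class templates perturb one base
amplitude/time-constant row by fixed sinusoidal class offsets scaled by a
single separability knob `delta`; `delta = 0` makes classes identical in
expectation. Volt scales are nominal (0–3 V). Defaults per sensor:
amplitudes (1.5, 2.2, 1.0) V, time constants (12, 20, 30) s, baseline
0.2 V, cycled for layouts with more sensors.

Three presets, each calibrated once by simulation and then frozen:

* `separable` (delta = 1.0, jitters 0.01, noise 0.005 V): every classifier
  family reaches 100% on the 7/5 split.
* `overlapping` (delta = 0.2, jitters 0.06, noise 0.02 V): an un-augmented
  ANN-3-50 averages ≈70% over seeds (observed 70.0% over a 10-seed
  calibration run) — hard enough that augmentation has room to help.
* `chance` (delta = 0): accuracy sits at the 1/C floor (≈16.7% for six
  classes).

What the generator does **not** emulate: baseline drift, the 400 s purge
tail, humidity/temperature covariates, heteroscedastic or correlated sensor
noise, and any physicochemical structure in how classes differ. Passing
tests on this generator therefore demonstrate the correctness and the
qualitative behaviour of the pipeline (augmentation improves mean accuracy
and reduces its variance in a small-sample regime), not the accuracy values
attainable on any real instrument's data.

## Numerical choices and degenerate inputs

* Alpha is sampled from the half-open uniform; endpoint inclusion is
  measure-zero and not distinguished.
* kNN ties break toward the lower trial index (stable sort), making
  augmentation bit-reproducible.
* Synthetic trials are never re-used as anchors or neighbours within one
  call (single-generation augmentation).
* A singleton training class is a hard error for the kNN methods, not a
  silent fallback.
* Stretch with α → 0 degenerates to the identity; the kept prefix is
  floored at 2 samples.
* σ = 0 Gaussian augmentation copies parents exactly.
* Experiment problem sizes default to the study shape (72 trials, 7/5
  split, sizes 0/100/500/2000, 10 repeats); the bundled verification runs
  use those sizes directly, with sub-sampled grids only for the CV sweep.

## Known limitations

The ANN's training internals (optimizer, patience, validation fraction) are
package choices; published accuracy tables obtained with other toolchains
cannot be matched number-for-number, and the harness targets the
directional effects instead. The adapter registry for externally deposited
datasets is a hook only — no dialect parser ships. RF tree depth is
unbounded, as is scikit-learn's default.
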