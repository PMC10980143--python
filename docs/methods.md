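# Methods

This note documents the models, conventions and numerical choices behind
`wristgait`, in the order data flows through the package.

## Problem setting

Walking leaves a quasi-periodic signature in a wrist-worn tri-axial
accelerometer: an oscillation at the step frequency (about 1.5–2.2 Hz in
older adults) with harmonics, superimposed on a slowly changing gravity
component and broadband non-gait arm movement. Gait detection assigns a
binary gait/non-gait label to each fixed-length signal window. The central
difficulty is that labeled free-living recordings are scarce while
unlabeled ones are abundant, which motivates the two-stage design:
self-supervised pretraining of a convolutional encoder on unlabeled
windows, then supervised fine-tuning of the same encoder with a linear
binary head on the labeled set.

## Preprocessing conventions

* Recordings are resampled to a canonical 30 Hz with polyphase/FIR rational
  resampling (anti-aliased), not naive decimation. Gait content lives below
  10 Hz, so 30 Hz retains it with margin.
* Windows are non-overlapping 10 s segments (300 samples at 30 Hz); a
  trailing partial window is dropped so every window has the fixed network
  input length.
* Annotation intervals are half-open `[start, end)` in seconds from the
  recording start; windows use the same convention. A window is labeled
  gait when gait intervals cover **at least half** of it — a tie at exactly
  5 s counts as gait (boundary-inclusive reading of the majority rule).
* Non-finite sample rows are dropped at ingestion with a logged count, not
  interpolated.
* Zero-mean/unit-variance whitening is a per-dataset flag
  (`WindowStandardizer`, scope `dataset` or `identity`). The default is
  whitening for unlabeled pretext data and identity for labeled data;
  whitening statistics are always fit on the training portion only.

## Synthetic signal generator

The generator (`wristgait.synthetic`) emulates the statistical structure
the detector exploits, not wrist biomechanics:

* **Gravity**: a unit vector drifting as a smooth random walk on the
  sphere (new orientation knot every 300 s, linearly interpolated on a 5 s
  grid), scaled to 1 g.
* **Gait bouts**: per-subject step frequency drawn uniformly from
  1.5–2.2 Hz; each bout is a three-harmonic sinusoid (relative amplitudes
  1 / 0.4 / 0.15, harmonics above 0.45·fs omitted as a real device's
  anti-aliasing stage would) mixed across axes by a random per-bout
  rotation, modulated by a slow envelope, with overall amplitude equal to
  the arm-swing parameter (default 0.25 g; lowering it emulates the
  reduced arm swing of parkinsonian gait). Bout durations are lognormal
  with mean ≈ 30 s (shape 0.6), floor 5 s, matching the scale of
  free-living gait sequences.
* **Non-gait activity**: second-order low-passed white noise (cutoff 8 Hz
  or 0.45·fs), RMS 0.12 g, covering ≈ 30 % of active time — broadband, so
  it is separable from gait by periodicity but not by energy.
* **Tremor**: optional 4–6 Hz sinusoid along a random axis.
* **Stillness** is gravity plus white sensor noise (SD 0.02 g); **non-wear**
  spans are a frozen gravity vector plus tiny noise (SD 0.003 g), placed in
  the night hours.
* Day structure: active period 07:00–23:00; per-day walking target either a
  fraction of active time (default 0.15) or an explicit minutes-per-day
  value, with ±4 % day-to-day jitter; one 60-min non-wear span per night.
  Bout intervals are recorded exactly and double as ground-truth
  annotations.

What the generator does **not** model: device calibration error and clock
drift, non-sinusoidal gait waveforms, periodic non-gait confounders
(cycling, rocking), posture-dependent gravity during walking, and
temperature-dependent noise. Tests passing on this generator therefore
show that the pipeline recovers the structure it is designed for; they do
not certify performance on real recordings.

Cohorts (`generate_cohort`) draw per-subject daily walking minutes from a
normal with the group mean and a 10-min between-subject SD (floored at
5 min), with age/sex/BMI covariates; a mild age–group trend (+2 years per
group index) gives the partial-correlation analyses something real to
adjust for. Group means within ≈ 10 % of targets at n = 20 follow from
SE = 10/√20 ≈ 2.2 min.

## Encoder and heads

The encoder is a 1-D pre-activation residual network: stem convolution
(kernel 5, stride 2), a stack of residual blocks (two 3-tap convolutions
each, BatchNorm + ReLU pre-activations, 1×1 projection shortcut on
stride/width changes), a final BatchNorm-ReLU, global average pooling and
a linear projection to the embedding. Two geometries are registered:

* **desk** (default; used by the test suite): 4 blocks, widths
  8/16/32/64, all stride 2, 64-d embedding — small enough that the full
  two-stage pipeline runs in minutes on one CPU core.
* **full**: 8 blocks, widths 64–512, 1024-d embedding — the reference
  geometry for an 18-layer network. The exact kernel/downsampling schedule
  of prior deep models is not reproduced; this adaptation is our own and is
  defined entirely by `EncoderConfig`.

Heads: a three-layer fully-connected head with or without interior ReLUs
(the two MLP pretext variants) and a single linear layer (gait output and
fine-tuning head).

The networks run on a small in-package numpy stack (`wristgait.nn`):
reverse-mode autodiff over vectorized primitives, convolution as
kernel-tap matmuls, fused train-mode BatchNorm, Adam. Gradients are
verified against central finite differences to 1e-4 in the tests.

## Self-supervised objectives

* **Multi-task pretext**: each window is independently reversed, segment-
  permuted (10-sample segments), time-warped and axis-scaled, each with
  probability 0.5 (maximum label entropy for the four binary tasks), in
  that fixed order so the flag semantics are deterministic. The loss is the
  mean of the four binary cross-entropies; chance level is ln 2.
  Parameterizations the task description leaves open: time warp is a
  strictly increasing piecewise-linear map with 4 interior knots and
  per-piece slopes log-uniform in [1/1.5, 1.5], re-interpolated to the
  original length with fixed endpoints; axis scales are log-uniform in
  [0.7, 1.4].
* **Contrastive pretext**: two views per window by uniform random 3-D
  rotations (axis uniform on the sphere, angle uniform on [0, 2π)),
  NT-Xent loss with cosine similarity and temperature τ = 0.1 (configurable;
  the value is our default, chosen once), projection head 32-d.

Optimization defaults for both: Adam, lr 1e-3, batch 64. With a frozen
backbone the encoder runs in eval mode, so neither weights nor BatchNorm
running statistics change — "frozen" is bit-exact.

## Fine-tuning

* Subject-wise 75/25 train/test split; an optional per-cohort minimum
  (default 3) for the test set. Within the training set, 80/20
  train/validation, again subject-wise.
* Grouped stratified k-fold (k = 5, 3 seeds): stratifying *windows* by
  class while grouping by subject is ill-posed at subject granularity, so
  folds stratify on subject-level gait-prevalence quantiles — subjects are
  ordered by prevalence, cut into bins of k, and each bin is dealt across
  folds.
* Training: all weights trainable, plain (unweighted) binary cross-entropy,
  early stopping when the validation loss has not reached a new minimum for
  5 consecutive epochs, best-epoch weights restored. Classification
  threshold 0.5.
* **Rotation augmentation**: during fine-tuning each training batch window
  is randomly re-oriented with probability 0.5. The gait label is invariant
  to sensor orientation while the raw signal is not; without this the
  encoder keys on per-subject orientation quirks and generalizes poorly
  across subjects. This is the package's own regularization choice,
  exposed as `rotation_augment` (default on).
* Model selection across configurations is keyed on F1, the appropriate
  summary under the strong gait/non-gait imbalance of daily living.

## Daily-living post-processing

* **Non-wear**: per-minute SD per axis (1-min epochs, 1-min stride); runs
  of ≥ 30 min with *every* axis below 13 mg (a standard actigraphy
  stillness bound) are non-wear.
* **Day selection**: full midnight-to-midnight calendar days with ≥ 20 h
  wear qualify; the first four qualifying days are used; fewer than four
  (i.e. under 96 h of usable data) excludes the subject — a returned
  status, not an exception.
* **Daily walking time**: per-day minutes = gait-window count × 10/60;
  windows inside non-wear spans are zeroed first (predictions off-body are
  meaningless); the summary is the median of the four per-day values
  (mean of the middle two). Windows, not merged bouts, are counted,
  consistent with the window-level pipeline.

## Statistics

* Confusion metrics are reported in percent; with positives present but
  none predicted, precision is reported as 0 with a `degenerate_precision`
  flag so F1 stays defined. Cohort-level reports average per-subject
  metrics, weighting participants equally.
* Kruskal-Wallis: scipy's tie-corrected H with a chi-square p
  (df = g − 1); the all-identical-values case is mapped to H = 0, p = 1.
* Dunn's post-hoc: pairwise mean-rank z statistics with the tie term
  Σ(t³ − t)/(12(N − 1)), two-sided normal p-values, Bonferroni
  multiplied by the number of pairs and capped at 1. Implemented in the
  package (with an independent textbook implementation as the test
  oracle).
* Partial correlation: Pearson correlation of least-squares residuals
  after projecting both variables on the covariates plus intercept;
  p from t with df = n − n_cov − 2; Spearman variant exposed. Sex enters
  as a binary indicator, BMI as continuous.

## Spectral baseline detector

`SpectralGaitDetector` is a logistic model on three per-window spectral
features: gait-band (1–3 Hz) power fraction, log total dynamic power, and
peak concentration (largest cadence-band bin over total dynamic power) —
the last separates strongly periodic walking from broadband activity of
similar band power. It is a first-class baseline and the workhorse for
day-scale cohort studies, where it is several hundred times cheaper than
the neural model; the neural pipeline's quality is established separately
on the supervised evaluation.

## Problem sizes and runtime choices

Everything below is a deliberate scale choice so the full suite runs on a
single CPU core; the statistical conditions (group means, sample sizes,
replicate counts, decision thresholds) are never adjusted per run.

* Supervised evaluation: 20 labeled training subjects + 10 held-out
  subjects, 20 min of active recording each (≈ 120 windows/subject);
  ≈ 2,000 unlabeled windows for pretraining (12 epochs); 3 fine-tuning
  seeds; label-efficiency comparison on 5 subjects over 5 seeds.
* Cohort studies run at a 10 Hz pipeline rate (windows of 100 samples):
  the generator's band content is capped below Nyquist, so detection
  statistics are unchanged while a 4-day, 60-subject replicate fits in
  ≈ 25 s. Cohort replicates: three groups at 60/45/30 min/day, n = 20
  each, 4 days per subject.
* The null calibration uses a literal single-group cohort (n = 20, one
  walking-duration distribution) randomly partitioned into three
  pseudo-groups after detection and summarization.

## Known limitations

* The generator's separability is optimistic relative to real wrist data;
  reported F1 values characterize the pipeline, not expected clinical
  performance.
* BatchNorm running statistics update during any train-mode forward pass,
  so a zero-learning-rate run has bit-identical weights but an
  epoch-to-epoch validation loss that is only approximately constant.
* The 18-layer/1024-d geometry is supported but not exercised by the test
  suite beyond shape checks.
* Dense per-sample labeling and gait-quality metrics (cadence, regularity)
  are out of scope.
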