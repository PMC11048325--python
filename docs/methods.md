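# Methods

`eegcaps` implements an EEG emotion-recognition pipeline whose two halves
are (i) a hand-crafted **multi-domain feature map** that fuses spatial,
spectral and temporal structure into one small tensor per analysis window,
and (ii) a **capsule-Transformer classifier** that reads a short sequence of
those tensors and outputs an emotion class.  This note records the model,
its assumptions, the parameters that matter, and the design decisions taken
where more than one reasonable choice existed.

## Signal model and preprocessing

Input is multichannel scalp EEG with 10–20 channel names, a sampling rate,
a per-trial label record (continuous valence/arousal ratings in [1, 9], or a
categorical negative/neutral/positive label), and optionally a leading
pre-trial baseline.  Preprocessing is deliberately minimal — no artifact
rejection, re-referencing or ICA:

1. **Downsampling** to a target rate (128 Hz for DEAP-style data, 200 Hz for
   SEED-style) via polyphase anti-aliased resampling
   (`scipy.signal.resample_poly`).  The output is truncated to
   `floor(n · target/rate)` samples so integer decimation is exact and trial
   duration is preserved to within one sample.
2. **Baseline trimming** removes the leading `baseline_seconds` (3 s for
   DEAP-style trials).
3. **Slicing** cuts each trial into non-overlapping windows (0.5 s
   DEAP-style, 1.0 s SEED-style); trailing remainder samples are discarded
   (floor semantics, never zero-padding).
4. **Grouping**: T = 4 consecutive slices of one trial form one
   recognition-cycle sample; groups never span trials.

The arithmetic this fixes: a 63 s trial at 128 Hz (8064 samples) loses its
3 s baseline, leaving 7680 samples = 120 windows; 40 trials give 4800 slices
and 1200 four-slice samples per subject.

## Per-window features

Each (channel, band, window) signal is summarized by three scalars:

* **Differential entropy**: `DE = ½ log(2πe σ²)`, σ² the unbiased sample
  variance.  This is the Gaussian closed form — a log-variance band-power
  surrogate, the standard reading for short band-limited EEG windows.  The
  log base is not dictated by the formula itself; we use the natural log
  (the convention in the DE-for-EEG literature), switchable to base 2 in
  `FeatureConfig`.  A variance floor of 1e-12 keeps DE finite on degenerate
  constant windows.
* **Sample entropy**: `SampEn = −ln(A/B)` with B the number of ordered
  template pairs of length m within Chebyshev tolerance r (self-matches
  excluded) and A the same at length m + 1, both counted over the N − m
  template start positions.  m and r are free parameters; we default to the
  field-standard m = 2, r = 0.2·sd(window).  When no template pair extends
  (A = 0 or B = 0) the statistic is undefined: `sample_entropy` returns NaN
  and logs a warning, and table/tensor consumers substitute a configurable
  finite ceiling (default 8.0) so downstream tensors stay finite.  On 0.5 s
  (64-sample) theta-band windows this happens regularly; it is a property
  of short regular windows, not an error.
* **PSD**: the periodogram `P(k) = |U(k)|²/N` of the window's DFT, reduced
  to one scalar.  The grid cell needs a single number and no reduction is
  canonical; we take the mean over positive-frequency bins (k = 1..N/2) of
  the already band-filtered window — the bands are isolated by filtering,
  so the mean tracks in-band power.  A `sum` reduction is available.

## The multi-domain feature map

Four canonical bands — theta 4–8, alpha 8–13, beta 13–31, gamma 31–50 Hz —
are isolated with an order-3 Butterworth bandpass applied forward and
backward (zero phase), so the four band copies of a window stay
time-aligned.  Filtering runs on whole trials before slicing, which is
equivalent to per-window filtering minus the per-window transients.

Per band and feature, channel scalars are placed on an **8 × 9 grid** that
preserves scalp anatomy (frontal rows on top, left hemisphere at left,
midline in the centre column).  Cells without an electrode are exactly zero;
no interpolation.  The two shipped layouts (`deap32`, `seed62`) are JSON
data files, documented and user-overridable; tests assert injectivity and
completeness rather than specific coordinates, because the placement is a
convention, not a standard.

The four band grids tile 2 × 2 — theta alpha / beta gamma, row-major — into
a 16 × 18 matrix, and the three per-feature matrices stack (DE, SE, PSD)
into the final **3 × 16 × 18** tensor.  The tile order is a recorded
convention: any consistent order presents the same information to the
network; only reproducibility requires fixing it.

Because DE (log scale), SampEn (≈0–2) and PSD (power units) are
incommensurate, occupied cells are z-scored per feature channel.  The
statistics are fitted on training folds only and applied frozen to test
folds; structural zeros stay zero.  A feature channel with zero variance is
left unscaled.

## Capsule encoder (per slice)

* **ConvReLU**: 256 kernels, 3 × 3, stride 2, valid padding, ReLU →
  256 × 7 × 8.  Valid (unpadded) convolution is used throughout; it is the
  only padding choice under which the stated kernel/stride counts produce
  consistent downstream shapes.
* **ECA** between ConvReLU and PrimaryCaps: global average pool to a
  channel vector, a 1-D convolution of channel-adaptive odd size
  k = |log₂C/γ + b/γ| rounded to odd (γ = 2, b = 1 defaults, giving k = 5
  at C = 256), sigmoid gating.  Shape-preserving.
* **PrimaryCaps**: 32 capsule channels × 8 planes as one 3 × 3 stride-1
  convolution (→ 256 planes over 5 × 6 positions), an SE block on those
  planes, then regrouping into 32·5·6 = 960 capsules of dimension 8 and the
  squash nonlinearity.  SE is defined on channel stacks, not capsule
  vectors, so "embedded inside the primary capsule" is implemented as
  acting on the convolutional planes before regrouping.  SE uses a
  bottleneck of C/r with r = 16 (r = 8 in the reduced-width configuration).
* **Squash**: `v = (‖s‖²/(1+‖s‖²))·s/‖s‖`, the canonical capsule
  nonlinearity (norms in [0, 1), zero maps to zero).  An ε = 1e-12 inside
  the square root keeps the gradient finite at s = 0.
* **EmotionCaps / dynamic routing**: each (primary i, class j) pair owns a
  full 16 × 8 transform; coupling logits start at zero (uniform couplings
  1/J), and each iteration applies softmax over classes, a weighted sum,
  squash, and a dot-product agreement update.  Iteration count is
  configurable, default 3 (the established choice); all iterations are
  differentiated through.  Routing weights initialize as N(0, 0.1²) from an
  explicit seed.

## Transformer temporal encoder (across slices)

Each slice's n_classes × 16 capsule outputs flatten row-major into one
token (d_model = 32 or 48); the T = 4 tokens of a sample form the sequence.
Six post-norm encoder layers with eight-head scaled dot-product
self-attention and a ReLU feed-forward block (hidden width 4·d_model),
each sublayer wrapped in residual + LayerNorm, re-encode the sequence; an
affine head on the concatenation of all T encoded tokens produces softmax
class probabilities.  Choices that the architecture description leaves
open, with our defaults: sinusoidal positional encoding on (temporal order
is the stated point of the module; a `none` switch exists for ablation),
post-norm arrangement (matching the add-&-norm depiction), FFN width factor
4 (Transformer convention), dropout 0.1.

## Training protocol

Cross-entropy loss, Adam (lr 1e-3 for DEAP-style runs, 1e-4 for
SEED-style), batch size 128, stratified shuffled 10-fold cross-validation
at the sample level.  Stratification is our choice (plain "ten subsets" is
ambiguous); it stabilizes metrics on small synthetic sets, and a
contiguous-in-time split can be obtained by passing precomputed folds.
Default epoch budget is 100 with optional early stopping (patience 10 on a
10% validation carve-out of the training fold); the scaled-down experiment
below disables early stopping and uses 30 epochs.  The best checkpoint is
the epoch with the lowest training loss, or validation loss when the
carve-out is active.  Binary labels derive from ratings by the threshold
rule *high iff rating > 5*; the boundary case rating = 5 is "low" (the
side is a convention; it is documented and configurable).  Metrics:
accuracy plus macro-averaged precision, recall and F1 from the confusion
matrix, reported per fold and as mean ± sd, percentages to two decimals.

All tensor computation runs on a small reverse-mode autodiff engine
(`eegcaps.nn`) written directly on numpy in float64: a deliberate design
that keeps the dependency surface minimal, makes runs bit-reproducible on a
CPU from a single integer seed, and is fast enough for the problem sizes
this package targets.  Its gradients are verified against central finite
differences, and the routing/attention paths against straight-line oracle
reimplementations, in the test suite.

## Synthetic data: what it does and does not show

The generator sums, per trial, four band-limited noise components (white
noise filtered by the same order-3 Butterworth bandpasses the pipeline
uses — generator and pipeline cannot disagree on band definitions) with a
1/f-like amplitude profile (theta 4.0, alpha 3.0, beta 1.5, gamma 1.0 RMS
units) plus a white-noise floor (sd 1.0).  Class c > 0 scales the
`effect_band` amplitude in `effect_channels` by (1 + c·effect_size), so
band power and DE carry a known, localized class signal.  Labels are
balanced; everything derives from an explicit seed.  A DEAP-shaped variant
produces 40 trials × 32 channels × 8064 samples at 128 Hz with a 3 s
baseline and uniform [1, 9] ratings, the class being derived downstream by
the threshold rule exactly as for real ratings.

Not simulated: eye-blink/EMG artifacts, volume conduction, non-stationarity
within trials, inter-subject variability.  Consequently, passing tests show
that the pipeline is implemented correctly and can learn a genuine
band-power class signal end to end; they say nothing about accuracy on real
recordings, which is why published-scale real-data accuracies are out of
scope here.

## Problem sizes used in tests and the acceptance script

The learning-sanity experiment uses 20 trials × 40 s at 128 Hz
(effect_size 2, gamma, eight effect channels) → 400 four-slice samples, a
reduced-width model (64 conv planes, 8 capsule channels × 8D, SE reduction
8, full 6-layer/8-head encoder), 30 epochs, no early stopping.  These sizes
are the package's chosen desk-scale study conditions: large enough that
chance-level initial loss (≈ln 2) and ≥95% training accuracy are meaningful,
small enough to run in a couple of minutes on one CPU.  The accounting
checks run at the full DEAP per-subject shape.

## Known limitations

* Real-data accuracies require licensed DEAP/SEED downloads and
  GPU-scale training of per-subject models; this package validates the
  method end to end on synthetic data only.
* Subject-dependent evaluation only; no cross-subject protocol.
* The SEED-style "fuse three time slices" variant of sample accounting is
  ambiguous in its source and is not implemented; the uniform
  4-slices-per-sample rule is used for both dataset styles.
* Electrode grid coordinates are a best-effort anatomical convention,
  shipped as replaceable data.
* The NaN-SampEn ceiling substitution (default 8.0) is a pragmatic bound;
  on very short windows the SE feature plane is partially saturated.
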