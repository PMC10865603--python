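# Methods

## Problem and model

The package stages sleep from a single continuous overnight PPG channel.
One recording is standardized to 10 h = 1200 epochs of 30 s, each epoch
resampled to 1024 samples, and the network maps the whole
1,228,800-sample sequence to per-epoch 4-class logits
(wake / light / deep / REM). Staging whole nights at once lets the model
exploit the slow bout structure of sleep; causality constraints (below)
keep each epoch's prediction a function of past and current signal only
where the architecture claims so.

Five components run in sequence:

1. **Local attention.** A causal convolution with kernel 7168 samples
   (= 7 epochs, i.e. the current epoch plus the preceding ~3 minutes,
   matching the classical 3-minute rule for light-sleep scoring), then a
   1×1 convolution down to one channel and a sigmoid. The resulting
   per-sample score in (0, 1) multiplicatively gates the input. The
   per-epoch attention score is the mean of its 1024 per-sample scores;
   sample resolution is kept for visualization. Causality is implemented
   by left padding of (kernel−1) samples, so the score at sample *t* sees
   samples ≤ *t* only; a perturbation more than 7 epochs in the past
   cannot change the current epoch's attention.
2. **InceptionTime feature extractor.** A stem convolution
   (1→32 channels, kernel 40, stride 20, ReLU) followed by six Inception
   blocks. Each block applies a 1×1 bottleneck feeding three parallel
   convolutions with kernels 5, 11, 23 (stride 1, same-length padding),
   plus a max-pool branch (k=3, stride 1) with a 1×1 projection taken
   from the block input; the four branches concatenate, so a block with
   branch width *f* emits 4·*f* channels. Block inputs are
   (32, 32, 64, 64, 128, 256) channels with branch widths
   (8, 16, 16, 32, 64, 128) and bottlenecks (8, 16, 16, 16, 32, 32):
   each block's output width 4·*f* equals the next block's input width,
   the only dimensionally consistent bookkeeping for those figures. Every
   block carries a residual shortcut (identity when input and output
   widths agree — blocks 1 and 3 — otherwise a 1×1 projection) and a ReLU
   on the sum. No batch normalization is used anywhere. The module ends
   with adaptive average pooling onto the 1200-step epoch grid and a 1×1
   convolution.
3. **Time-distributed dense layer**: a per-epoch linear map (implemented
   as a 1×1 convolution), no nonlinearity.
4. **Temporal convolutional stack**: five residual blocks at epoch
   resolution, each two dilated causal convolutions (64 channels, kernel
   8, dilations 1, 2, 4, 8, 16) with ReLU and dropout 0.2 after each, and
   a 1×1 downsample on the residual path where widths differ. Causal
   padding uses the standard construction (pad left by
   (k−1)·dilation); the stack's receptive field is
   1 + (8−1)·2·(1+2+4+8+16) = 435 epochs into the past.
5. **1×1 convolutional head** to 4 classes; softmax for probabilities.

### Width calibration

Three widths are not derivable from the figures above: the attention
convolution's channel count, the width of the 1×1 convolution after the
adaptive pooling, and the dense width. They were fixed by requiring the
default network to total exactly 1,922,397 trainable parameters under the
per-block-residual reading: **attention 124, inception head 256, dense
104**. An exhaustive search over these widths and the structural variants
(residual every block vs. every third block, always-projected shortcuts,
weight-normalized temporal convolutions, bottlenecked pooling branch)
shows this is the parameter total's unique solution with the per-block
residual convention and a power-of-two inception head; no solution exists
with dense width 64. `tests/test_acceptance.py` pins the count.

## Numerical core

The network and its gradients are implemented directly on numpy/scipy.
Convolutions use an im2col strided view for short kernels and an
rfft-based cross-correlation for kernels ≥ 128 samples (the attention
kernel), chunked over output channels to bound memory; forward passes in
evaluation mode cache nothing, so a full-width forward fits comfortably
in memory. Weights are float32 with fan-in-scaled uniform initialization
from a seeded generator; a float64 mode exists and is used by the
finite-difference gradient checks (every layer and the end-to-end chain
are verified against central differences). Optimizers are RMSprop
(α = 0.99) and Adam (β = 0.9/0.999), both with ε = 1e-8, learning rate
0.001, batch size 2 (whole recordings), and no schedule or early
stopping. Dropout masks come from a dedicated generator reseeded at the
start of each training run, so fixed seeds reproduce loss trajectories
bit-for-bit on one platform.

The loss is a class-weighted negative log-likelihood over masked-in
epochs, normalized by the summed weights of contributing epochs (a
weighted mean, so the scale is comparable across class mixes). Class
weights are inverse frequencies w_k = N/(4·N_k) over the training set's
masked-in epochs, which satisfy Σ w_k·N_k = N. Padded or unscored epochs
have exactly zero gradient (asserted analytically in the tests).

## Preprocessing

Order: zero-phase low-pass filter → polynomial detrend → min-max rescale
→ polyphase resample → length standardization.

- **Filter**: 8th-order Chebyshev type II, 8 Hz stop-band edge, 40 dB
  attenuation, applied forward-backward (`sosfiltfilt`), so pulses keep
  their temporal position; requires fs > 16 Hz.
- **Detrend**: subtract a least-squares degree-10 polynomial over the
  full record, with the abscissa rescaled to [−1, 1] (raw sample indices
  make the degree-10 design matrix numerically singular; the rescale is
  mathematically neutral).
- **Rescale**: (x−min)/(max−min) per recording over the whole night —
  per-epoch scaling would erase the amplitude dynamics that carry stage
  information. Constant signals are rejected.
- **Resample**: each 30-s epoch must hold exactly 1024 samples, i.e.
  1024/30 ≈ 34.133 Hz. A nominal figure of 34.3 Hz rounds this; the
  epoch sample count is load-bearing (the attention kernel is 7 × 1024),
  so the grid is exact by construction via rational polyphase resampling
  (e.g. 128 Hz → up 4 / down 15). A trailing partial epoch is discarded.
  Because resampling ringing can overshoot [0, 1] slightly, the unit
  rescale is re-applied afterwards; it is idempotent on range, so this
  is the only deviation from the prose order and it changes nothing
  else.
- **Standardize**: keep the first 1200 epochs of longer recordings; pad
  shorter ones with zero epochs at the end, masked out of loss, metrics
  and sleep parameters.

## Uncertainty and selective prediction

Energy is computed per epoch from its 4 logits with an overflow-safe
log-sum-exp; temperature defaults to 1 (no tuned value is reported for
this architecture). The threshold τ is the lower empirical quantile of
the pooled training-epoch energies at the kept fraction (order statistic
at ⌈keep·n⌉), an unambiguous convention reproducible across numeric
stacks; keep = 1 gives the training maximum. Rejection operates per
epoch — the logits, the only input to the energy, exist per epoch.
Accepted means E ≤ τ; rejected epochs keep their argmax prediction for
audit but are excluded from metrics and sleep parameters; masked-out
epochs are neither.

The calibration experiment in the tests uses a converged reduced-width
model (40 training epochs): the energy ordering of a half-trained model
is not yet informative, which is expected — the energy score is a
property of a fitted classifier. The learnability smoke test uses the
shorter 20-epoch budget.

## Evaluation

Accuracy generalizes the binary form to multiclass trace-accuracy;
Cohen's κ uses Pr(a) = accuracy and Pr(e) = Σ_k row_k·col_k / N²;
weighted F1 averages per-class F1 = 2TP/(2TP+FP+FN) by support. κ returns
NaN when Pr(e) = 1 (degenerate one-cell agreement). Pooled metrics are
epoch-pooled across subjects; per-subject reports enable
subject-averaging. The rejection breakdown divides, per (truth,
prediction) cell, the rejected count by the pre-rejection count, with NaN
for empty cells. Sleep parameters: TST = 0.5 min × (light+deep+REM epoch
count) over masked-in (and accepted, when selective) epochs; stage
fractions are percentages of TST and sum to 100 when TST > 0; an all-wake
night reports zeros with a `defined=False` flag instead of raising.
Correlations across subjects are Pearson r (and r²) per parameter.

## Synthetic data

The generator emulates what makes PPG stageable: (i) hypnograms from a
first-order Markov chain over the six R&K stages starting in wake, with
self-transition probability 0.90 and jump probabilities proportional to a
target occupancy near overnight cohort medians (wake ≈ 34%, light ≈ 39%,
deep ≈ 12%, REM ≈ 11%, matched loosely); (ii) a pulse train whose beat
intervals are Gaussian with stage-group-dependent mean and coefficient of
variation — wake 72 bpm / CV 0.10, light 62 / 0.06, deep 56 / 0.03, REM
68 / 0.12 — floored at 0.3 s; (iii) a fixed asymmetric pulse template
(systolic peak plus dicrotic shoulder) amplitude-modulated by a 0.25 Hz
respiration sinusoid, deeper in non-REM; (iv) sinusoidal baseline wander
(amplitude 0.05, period 60 s) and white noise (σ = 0.02). S1/S2 and
S3/S4 share their group's pulse parameters; the six-class distinction
exists to exercise the label mapper. Durations default to 8–10 h drawn
uniformly at 128 Hz; everything is driven by one seed, and the generator
logs its own beat times and stages so tests can check interval statistics
and peak-aligned attention without a detector.

These values are direction-faithful to sleep physiology but are
configuration, not claims. The generator does **not** emulate motion
artifacts, arrhythmias, sensor dropouts, inter-subject morphology
differences, or realistic 1/f noise — so passing tests demonstrate that
the pipeline is implemented correctly and that the architecture can
exploit rate/variability cues, not that cohort-level staging accuracy
transfers to real recordings.

## Study sizes used in tests

The test suite trains reduced-width models (attention 4, stem 8, branch
widths 2–16, head/dense/TCN width 16) on 12 synthetic 2-h subjects with 4
held out, batch size 2 — sizes chosen so the whole suite, including two
training runs, completes in a few minutes on one CPU while leaving the
learnability margin wide (held-out accuracy ≈ 0.85 after 20 training
epochs vs. a ≈ 0.38 stage-prior baseline). The full-width default
network is exercised for the parameter count and one complete 10-h
forward pass.

## Known limitations

- The three calibrated widths reproduce the published parameter total
  but are not uniquely implied by the architecture description; other
  (width, residual-placement) combinations could match it under
  different structural readings.
- Cohort-scale claims (accuracy/κ on real polysomnography datasets) are
  out of scope here: they require restricted-access data and GPU-scale
  training. Nothing in this package should be read as reproducing them.
- The EDF writer is minimal (16-bit, integer sampling rates, 1-s
  records, single channel per file as written); reading uses mne and
  accepts general EDF/EDF+.
- Training is CPU-bound numpy; it is intended for the reduced
  configurations and synthetic-scale experiments, not for full-cohort
  optimization.
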