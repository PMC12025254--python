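# Methods

This note records the model, the preprocessing conventions, the synthetic
data generator, and the numerical and design choices behind them. It is the
reference for what the package computes and what its tests do and do not
demonstrate.

## The classification problem

The package targets binary classification of 16-channel EEG epochs into
pre-training vs post-training sessions of a memory-training study design.
The unit of classification is a 2 s epoch of band-filtered signal
(16 channels x 2000 samples at 1 kHz). A model is trained once per
frequency band on band-filtered copies of the data, using the canonical
seven-band table: Delta 1–4, Theta 4–8, Alpha1 8–10.5, Alpha2 10.5–13,
Beta1 13–20, Beta2 20–30, Gamma 30–50 Hz.

The sampling rate is fixed at 1000 Hz throughout: a 2 s analysis window
containing 2000 sample points forces it, and every window/step parameter is
expressed in seconds so other rates remain configurable.

## DU-former

The network composes four parts.

**Dual-branch convolutional front end.** Both branches share the printed
kernel shapes: a 1x25 temporal convolution applied per electrode, then a
16x1 spatial convolution collapsing the electrode axis. The "large" branch
uses temporal stride `temporal_stride` (default 5), batch normalization and
ReLU; the "small" branch uses a finer stride (default 1), ReLU, then a
non-overlapping max-pool over tokens whose width is solved so its token
count equals the large branch's (the token axis is right-padded by edge
replication when the counts do not divide evenly), followed by layer
normalization. The two token sequences are fused by elementwise sum
(concatenation followed by a linear projection is available behind
`fusion="concat"`).

**Separable multi-head self-attention (SMHSA).** Per head: a d→1 projection
produces a scalar context logit per token; a softmax over the token axis
turns these into context scores; the K projections are pooled into a single
context vector by score-weighted summation; the output rows are
ReLU-activated V projections gated elementwise by the (broadcast) context
vector. Heads are concatenated and linearly projected. Cost is linear in
token count; no token x token matrix is formed. The gate activation is ReLU
by default (`attention_gate="sigmoid"` is available). Two pre-norm residual
encoder blocks are used: `y = x + SMHSA(LN(x))`, `z = y + FFN(LN(y))`, with
a two-layer FFN of expansion ratio 4. Pre-norm placement was chosen for
training stability; the residual arrangement is a design choice of this
package.

**Gaussian reparameterization head.** The mean branch applies a 1-D
convolution (kernel 3) over the token axis, average-pools the tokens, and
layer-normalizes to give mu; the variance branch average-pools and
layer-normalizes the raw tokens. Because layer normalization emits negative
values, the standard-deviation vector is `softplus(.) + 1e-4`; the floor
guarantees strict positivity. During training and Monte-Carlo inference the
embedding is sampled as `S = mu + eps * sigma` with `eps ~ N(0, I)` drawn
per sample; deterministic inference uses `S = mu`. Point predictions are
always deterministic; the stochastic path is reserved for training and the
uncertainty analysis.

**Classifier and loss.** A linear map to 2 logits with softmax. The
training loss is cross-entropy plus an optional regularizer
`kl_weight * KL(N(mu, diag sigma^2) || N(0, I))` with closed form
`0.5 * sum(sigma^2 + mu^2 - 1 - ln sigma^2)`, averaged over the batch
(default weight 1e-4; zero recovers plain cross-entropy). The KL term
prevents the variance branch from collapsing.

Hyperparameters that the architecture description leaves open — filter
count (32), embedding size (= filter count), 4 heads, FFN ratio 4,
optimizer (Adam, 1e-3), batch size (32), epoch budget (<=100 with early
stopping on a 10% stratified validation split carved from the training
folds) — are exposed in `ModelConfig` / `TrainConfig`, never hard-coded.

### Ablation semantics

`use_smhsa=False` replaces the attention sublayer with the identity, so
each encoder block reduces to a residual FFN; everything else is intact.
`use_reparam=False` feeds the token-averaged encoder output directly to the
classifier. Ablation runs share fold assignments and seeds with the full
model.

## Preprocessing

Stage order: broadband zero-phase Butterworth band-pass (0.5–50 Hz, 4th
order) → ocular artifact removal → myogenic suppression → bad-channel
interpolation → seven-band split (zero-phase 4th-order band-passes) →
sliding-window epoching (2 s window, 1 s step; a recording of T samples
yields `floor((T-W)/S)+1` epochs). All filters run forward-backward, so
phase is exactly zero and the effective magnitude order doubles; filter
reports record this.

Ocular removal: seeded FastICA (as many components as channels, tol 1e-4,
cap 500 iterations) decomposes the recording; components whose absolute
Pearson correlation with a reference trace exceeds 0.8 are zeroed before
back-projection. The reference trace is band-pass filtered identically to
the data first — the 0.5 Hz high-pass reshapes slow blink transients, and
correlating against an unfiltered template systematically underestimates
the match. Myogenic suppression zeroes components whose fraction of Welch
power above 30 Hz exceeds 0.6; this transparent spectral criterion replaces
template matching against a muscle-pattern library, which would require
hardware-specific templates. Both stages are optional and off by default:
they are enabled per run, so a cleaning pipeline and a pass-through
pipeline differ only in those stages. On signals dominated by near-Gaussian
narrowband activity the FastICA rotation within the Gaussian subspace is
not identifiable and the iteration cap is routinely reached; the
decomposition is still usable and is used, with the event recorded in the
removal report. Only a numerically invalid decomposition causes the stage
to return its input unchanged with a warning status.

Bad channels are an explicit user input (impedance-based detection is
hardware-side) and are reconstructed by spherical spline interpolation
(Perrin-style, order m=4, 7 Legendre terms, slight diagonal loading for
conditioning) using standard 10-10 unit-sphere electrode coordinates
embedded in `montage.py`. A test cross-checks the reconstruction against
mne's implementation on a smooth field.

## Synthetic EEG generator

The generator emulates the statistical structure the pipeline consumes, not
the biophysics of any particular cortex:

* per band, three narrowband sources (white Gaussian noise band-passed to
  the band edges, unit variance) mixed into the 16 channels through a fixed
  random mixing matrix drawn once per seed (rows normalized so each
  channel's oscillation variance equals the band amplitude squared);
* per channel, 1/f^alpha background noise (alpha = 1, spectral slope
  flattened below 1 Hz to bound DC power), standard deviation 3 uV;
* default band amplitudes (uV): Delta 20, Theta 10, Alpha1 10, Alpha2 8,
  Beta1 6, Beta2 5, Gamma 4 — a descending profile typical of scalp EEG.
  With these values each band's own oscillation dominates that band's
  measured power, so a variance ratio injected in a band appears as
  approximately the same measured band-power ratio;
* the class contrast multiplies the oscillation variance of one band
  ("post" class) by `effect_ratio`; at ratio 1 the class generators are
  identical by construction;
* optional artifact events: blink-like Gaussian pulses (~300 ms, default
  150 uV, 15/min) with a frontally dominated spatial profile, and >30 Hz
  noise bursts (0.3–0.8 s, temporally weighted) for the myogenic case. The
  contaminated recording carries its clean signal and the injected source
  trace for residual-error assessment.

Everything is reproducible from `(seed, subject_id, class_label)`.

What the generator does *not* model: inter-subject amplitude or topography
differences, non-stationarity within a recording, event-related dynamics,
realistic source geometry, or line noise. Consequently, passing the
classification experiments here demonstrates that the pipeline and model
can detect and exploit a band-limited power contrast end to end — it does
not certify performance on human EEG, where the contrast is weaker,
subject-dependent, and entangled with confounds.

## Evaluation protocol

Ten-fold cross-validation with two granularities. Segment-level stratified
folds are the API default. Subject-wise folds (all of a subject's epochs in
one fold) are used for the package's own acceptance experiments: with a 2 s
window and 1 s step, adjacent epochs share half their samples, and epochs
of one recording share its noise realization, so segment-level splitting
leaks test content into training — measurably, a band carrying no class
signal scores ~0.6 instead of 0.5 under segment folds in this codebase.
Subject-wise splitting restores the chance level on null data. Which
granularity a published protocol used is often unknowable; both are
first-class here and the leakage is documented rather than hidden.

Metrics: accuracy, precision, recall, F1 (sklearn), AUC by the rank
statistic over positive-class scores; AUC is reported as missing (NaN) when
a test fold contains one class. Training is deterministic given a seed; the
evaluation path uses deterministic embeddings (S = mu).

The desk-scale experiment preset (`ModelConfig.reduced()` /
`TrainConfig.reduced()`): 16 filters, 16-dim tokens, temporal strides 20/5
(large/small branch), dropout 0, fixed 15 epochs, batch 64, lr 1e-3, no
early stopping. Problem size for the bundled experiments: 10 subjects x
21 s per recording -> 20 epochs per recording, 200 epochs per class;
leave-one-subject-out folds. These sizes were chosen once as the smallest
configuration on which the classification contrasts of interest are stable.

## Prediction uncertainty

K = 30 stochastic forward passes (fresh eps per pass) yield a mean
probability vector per epoch; the per-epoch uncertainty level is the
normalized predictive entropy `H(p_bar)/ln(n_classes)`, which is 0 iff the
mean prediction is degenerate and 1 iff it is uniform. This definition is
an interpretation: entropy of the MC mean is bounded, class-count
invariant, and reduces to softmax confidence when sigma -> 0. The MC
standard deviation of the top-class probability is reported alongside as an
alternative spread measure. At K = 30 the sampling noise of the entropy
estimate is small relative to the 0.1-wide histogram bins used in the
occurrence-rate plot. The acceptance-rate summary is the fraction of epochs
with uncertainty <= 0.3; it is non-decreasing in the threshold by
construction.

## Numerical implementation

The networks (DU-former and the CNN / depthwise-separable /
quadratic-attention baselines) run on a small reverse-mode automatic
differentiation engine over numpy arrays written for this package
(`duformer.nn`): broadcasting arithmetic, batched matmul, strided 1-D
convolution via windowed BLAS matmul, max-pooling, reductions, softmax with
detached-max stabilization, and Adam. Every primitive is verified against
central finite differences; the separable attention is additionally checked
against an explicit brute-force evaluation, and the quadratic-attention
baseline serves as the conventional-attention reference. Float32 is used
for model state, float64 for gradient checks. Inputs are scaled by a single
scalar (the training-set standard deviation, stored with the model) so
activations are O(1) without erasing the amplitude differences that carry
class information — per-epoch standardization would destroy the signal of
interest.

Degenerate inputs: recordings shorter than one window yield an empty epoch
set with a warning; a single-class training set, an empty test set, an
unknown band/baseline/artifact name, and cutoffs at or above Nyquist raise
errors naming the offending value. The Mann-Whitney U test uses midranks;
its two-sided p-value is exact for small samples (count-distribution
recurrence without ties; full enumeration with ties while the assignment
count is tractable) and otherwise uses the normal approximation with tie
and continuity corrections, which at n = m = 8 tracks the exact value to
about 0.01 in the tails.

## Known limitations

* The synthetic class effect is one-dimensional (a band-power ratio);
  models that read mean band amplitude already classify it well, so
  architecture comparisons on this data compress toward the ceiling and
  ablation margins can invert relative to real-data behavior. In our
  subject-wise runs, removing the reparameterization head costs ~9 accuracy
  points while removing attention costs nothing — attention is redundant
  for a linear power cue.
* EDF output quantizes to 16 bits over a symmetric per-channel range.
* The EDF writer requires integer sampling rates and whole seconds of
  signal (1 s data records).
* FastICA component count always equals channel count; no dimensionality
  or component-count selection is attempted.
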