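# Methods

## Pipeline overview

`ppgarr` classifies 10-s, 100-Hz PPG segments into six rhythm classes
(SR, PVC, PAC, VT, SVT, AF; labels 0–5). The pipeline is: derivative-based
multi-view enhancement → per-segment z-scoring → two-stage stratified
splitting → a 1-D VGG or VGG-BiLSTM network trained with Adam and early
stopping → a confusion-matrix metric suite with 95% confidence intervals.
A synthetic six-rhythm simulator provides data with the statistical
structure the classifier must exploit, so everything is testable without
clinical recordings.

## Multi-view enhancement (signals)

The velocity and acceleration plethysmograms are first-order backward
differences (`VPG[i] = PPG[i] − PPG[i−1]`, `APG = ΔVPG`), causal by
construction. The first sample has no predecessor; two boundary rules are
provided. The default, `extrapolate_continuous`, repeats the first interior
difference (`out[0] = x[1] − x[0]`), which keeps the derivative of a linear
ramp constant — the behaviour a continuity-preserving extrapolation should
have. The alternative `literal_eq1` (`out[0] = x[0] − (x[1] − x[0])`)
mirror-extrapolates a virtual sample before the segment; on a ramp it
produces a sign flip at index 0. Both are exposed because the two
conventions appear in practice; the continuous rule is the default.

Derivatives are computed from the raw segment, and each of the three
channels is then z-scored independently. Per-channel normalization matters
because VPG and APG amplitudes are orders of magnitude below the raw PPG;
without it the derivative channels would be numerically invisible to the
first convolution. The z-score uses the population (denominator N)
standard deviation — with 1000 samples per segment the difference from the
sample estimator is negligible, but the convention must be fixed for exact
tests. A segment whose standard deviation falls below 1e-8 (e.g. a sensor
dropout recording a constant) yields an all-zero channel and a `degenerate`
flag rather than an error, so batch pipelines keep running.

## Stratified splitting (dataset)

The 60/20/20 split is two-stage: each class is first divided 60:40 into
train vs. a temporary pool, then the pool is halved per class into
validation and test. Fractional per-class allocations are resolved by
largest-remainder rounding within each stage, which keeps every
partition's per-class count within 1 of `ratio × count(class)`; when a
class's temporary pool is odd, validation receives the extra sample (an
arbitrary but fixed tie-break). Shuffling uses a generator seeded by
`(seed, class)`, so results are deterministic and independent of class
iteration order. Classes with fewer than three members make a three-way
stratified split infeasible and raise an error naming the class. Splitting
is segment-level, not subject-level; a patient-grouped splitter is a known
limitation, not provided.

## Architectures (models)

The backbone is three VGG-style blocks (two conv(k=3, same padding) +
BatchNorm + ReLU units, then stride-2 max pooling) with widths 64/128/256,
taking the temporal axis 1000 → 500 → 250 → 125. The hybrid adds two
stacked bidirectional LSTM layers (128 hidden units per direction) on the
transposed (batch, time, channels) sequence; per-step outputs concatenate
the forward and backward hidden states (width 256), and flattening
256 × 125 gives the 32,000-wide classifier input — identical to the
baseline's flatten, so the 4096–4096–6 softmax classifier is shared
between both variants. Initial LSTM hidden and cell states are zero (the
conventional choice; nothing else is specifiable without further
information). Dropout (50%) is applied only in the classifier; no dropout
is inserted between the stacked recurrent layers. `input_channels=1`
selects the PPG-only input; `use_backbone=False` yields the pure-recurrent
variant used as an ablation arm.

The networks run on a small NumPy engine (`ppgarr.nn`) written for this
package: im2col convolution, batch normalization over batch and time,
non-overlapping max pooling, inverted dropout, a BPTT bidirectional LSTM
and Adam. Every layer's analytic backward pass is verified against central
finite differences in the test suite, on float64 inputs where the check is
meaningful to ~1e-7. Weight initialization: He-scaled normals for
convolutional and hidden linear layers, Xavier for the output layer,
uniform ±1/√H for LSTM matrices with forget-gate biases at 1. Batch
normalization uses momentum 0.1 and eps 1e-5; all such constants are
recorded in the run manifest.

Networks output probabilities (softmax is part of the model); training
differentiates the clipped cross-entropy through the softmax layer, which
reproduces the fused `(p − y)/N` logit gradient exactly while keeping the
documented interface at the probability level (log clipping floor 1e-12).

## Training (training)

Adam (β = 0.9/0.999, eps 1e-8) with learning rate 1e-4, batch size 32, at
most 200 epochs, minibatch order reshuffled each epoch from a seeded
generator (seed 42 everywhere by default). Early stopping terminates
training after 20 consecutive epochs without a strict validation-loss
improvement (`min_delta = 0`, the weakest reading of "no improvement"),
and the best-validation-loss weights are restored — returning overfit
final-epoch weights would defeat the purpose of stopping early. No
learning-rate schedule is applied: only an initial rate is specifiable,
and no decay rule is defined. Class weighting and oversampling are
deliberately absent; imbalance is addressed by stratified splitting alone.
A non-finite loss aborts with the epoch and batch named. Every run can be
persisted as a checkpoint (NPZ weights + JSON sidecar with the full
config, seed, best epoch and validation loss), a history CSV and a
manifest sufficient to re-plot the training curves.

## Evaluation (evaluation)

The 6×6 confusion matrix uses rows = true class, columns = predicted.
Per-class metrics come from the one-vs-rest decomposition; zero
denominators yield an explicit "undefined" (rendered as an em dash), never
a silent zero. 95% confidence intervals are Wald normal approximations on
each metric's natural denominator: the class's true count for sensitivity
(and, as a documented approximation, for F1 — no delta method), the
negative count for specificity, the predicted count for precision, and the
total for overall accuracy. Macro rows are unweighted class means with
`mean ± 1.96 · s/√C`, where `s` is the across-class sample standard
deviation. These methods were frozen after verifying they reproduce the
reference interval pairs built into the acceptance tests. Reports round
half-up to one decimal (banker's rounding would misreport a mean ending in
.45), with a 1e-9 guard absorbing binary representation error.

## Synthetic data (simulate)

Each segment is a beat train rendered as Gaussians. RR intervals are
normal with a 0.25-s floor (clipping, which prevents overlapping beats);
ectopic beats arrive early by `prematurity × RR`, carry their own
amplitude/width multipliers, and (for PVC) are followed by a compensatory
pause restoring the underlying phase. Class parameters: SR 0.8 ± 0.03 s;
AF 0.8 ± 0.20 s (irregularly irregular); PVC = SR plus 15%-per-beat
ectopy, prematurity 0.35, amplitude ×1.4, width ×1.5, compensatory pause;
PAC likewise with amplitude ×0.8, width ×1.0, no pause; VT 0.35 ± 0.02 s
with amplitude ×0.6 and width ×1.6 (merged, widened pulses); SVT
0.35 ± 0.02 s with normal morphology.

Rendering: a systolic Gaussian per beat — the stated 0.10 s pulse width is
interpreted as full width at half maximum (σ ≈ 0.0425 s), a physiological
systolic peak width; a σ of 0.10 s would merge even SVT pulses and destroy
the rate signature — plus a dicrotic Gaussian at 0.35× amplitude delayed
0.25 s with the same σ. Additive white Gaussian noise (sd 0.05) and
sinusoidal baseline wander (amplitude 0.3, 0.25 Hz, random phase) are
scaled relative to the unit systolic amplitude; both are plausible
mid-range values for finger-PPG at rest. Per-beat amplitudes get ~5%
multiplicative jitter. Per-segment generators derive from
`SeedSequence([seed, class, index])`, so datasets are bit-reproducible and
single segments can be regenerated in isolation.

What the simulator does *not* emulate: real PPG morphology-from-physiology
(pulse transit effects, respiratory amplitude modulation), motion
artifacts, sensor transfer functions, or sample-correlated (band-limited)
sensor noise — the white noise used here is spectrally flat, which makes
the derivative channels noisier than derivatives of real, inherently
smooth PPG. Passing tests therefore demonstrate that the pipeline learns
and evaluates correctly on data with the intended timing/morphology
statistics, not that it reaches any particular accuracy on clinical
recordings.

## Desk-scale experiments and their interpretation

The bundled ablation (`ppgarr.experiments`, CLI `ppgarr ablation`) trains
four arms — pure BiLSTM, pure VGG, hybrid on PPG only, hybrid on the full
multi-view stack — on one shared synthetic dataset of 600 segments
(100/class) with a reduced network (widths 16/32/64, 32 hidden units per
LSTM direction, one 256-unit classifier layer), Adam at 1e-3, batch 32,
up to 30 epochs. These sizes keep a single run in the low minutes on one
CPU core.

A scale caveat, measured with this package on its own simulator: with 360
training segments the reduced hybrid memorizes the training set (training
loss < 0.1) while test accuracy plateaus in the mid-60s — the rate classes
(VT, SVT) are learned perfectly, but the beat-timing classes (SR, PVC,
PAC, AF) require more examples than 60 per class to generalize. The same
model and settings trained on 3000 segments (500/class) exceed 85% test
accuracy within 12 epochs (see the moderate-scale test in
`tests/test_acceptance.py`). Conclusions about architecture ordering at
the 600-segment scale are therefore unstable, and the desk-scale
experiment should be read as an integration exercise of the full pipeline,
not as a measurement of achievable accuracy.

## Numerical and design choices

* float32 tensors throughout training (float64 in gradient-check tests).
* Max pooling uses floor division; a trailing odd sample receives zero
  gradient.
* Degenerate z-score tolerance 1e-8; cross-entropy log clipping 1e-12.
* Ties in largest-remainder allocation go to the earlier partition
  (train in stage 1, validation in stage 2).
* The softmax subtracts the row maximum before exponentiation.
* Internally LSTM gates are ordered (input, forget, output, cell) so each
  activation applies to one contiguous block; this is an implementation
  detail invisible at the interface.

## Known limitations

* Segment-level splitting can place segments of one subject in different
  partitions; subject-grouped splitting is out of scope.
* The F1 confidence interval reuses the binomial machinery on a
  non-binomial quantity; it is an approximation, flagged in the API docs.
* The NumPy engine is single-threaded except where BLAS parallelizes
  matrix products; full-scale (64/128/256-width) training is impractical
  on CPU and out of scope. The full-size architecture is still
  constructed and shape-verified in tests.
* The simulator's rhythm classes are caricatures built from beat-timing
  statistics; morphological subtleties that distinguish real PVC from PAC
  (pulse-wave shape changes beyond amplitude/width scaling) are not
  modeled.
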