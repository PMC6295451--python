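# Methods

## Problem and states

The package performs segment-based seizure detection: every 1-s window
of a multichannel EEG recording is assigned to one of three states.
Ictal seconds are those overlapping an expert-annotated seizure
interval `[onset, offset)`. Preictal seconds are the `preictal_len_s`
seconds immediately before an onset, truncated at the record start or
at a preceding seizure's offset. Interictal seconds must lie at least
`interictal_margin_s` from any seizure; closer seconds that are neither
ictal nor preictal are excluded outright rather than mislabeled as
baseline. Intervals are half-open so no sample is labeled twice, and
epochs are aligned to whole seconds so none spans a state boundary.

There is no universal preictal duration or interictal distance
criterion in the clinical literature; both are exposed as parameters.
The defaults (1800 s preictal, 3600 s margin) are conservative values
appropriate for hour-scale clinical records; the synthetic experiments
use 4 s / 4 s to match their compressed timelines.

## Signal domains

Time-domain inputs are the raw channels × samples grid of one epoch
(6 × 256 at the default 256 Hz). Frequency-domain inputs are the
per-channel one-sided FFT amplitude spectrum, `B = L/2 + 1` bins at
`fs/L` Hz spacing, with amplitudes scaled `2|X[k]|/L` (and `|X[k]|/L`
at DC and Nyquist) so a bin-aligned sinusoid of amplitude `A` appears
as exactly `A`. Choices the transform leaves open were fixed as
follows: no taper (rectangular window) — spectral leakage is acceptable
at 1-s resolution and the raw definition keeps the amplitude semantics
exact; the DC bin is retained, since the network can learn to ignore
it; spectra stay in a channels × bins grid so the identical 2-D network
consumes both domains.

## Network

A three-layer CNN, `conv → mean-pool → fully connected`:

* convolution: 6 kernels of 5×5, stride 1, valid (no padding), one bias
  per map. Channels form the grid's first axis, so a kernel mixes 5
  adjacent channels × 5 adjacent samples/bins; channel order matters
  and is recorded with the model.
* pooling: non-overlapping 2×2 arithmetic mean; odd trailing rows or
  columns are truncated, not padded.
* output: fully connected sigmoid, one score per class in (0, 1);
  prediction is the argmax with ties broken toward the lowest class
  index (interictal < preictal < ictal).

There is no nonlinearity between convolution and pooling by default;
`conv_sigmoid=True` inserts one, and the analytic gradients cover both
variants. The loss is the mean over classes of squared error against a
one-hot target, averaged over the batch. Optimization is plain
minibatch SGD (default learning rate 0.01, batch 16, at most 100
epochs), with seeded uniform Glorot initialization
(±√(6/(fan_in+fan_out))) and early stopping when the per-epoch MSE has
not improved by `tol = 1e-5` for `patience = 10` consecutive epochs.

Inputs are standardized per feature (per channel × column position)
using statistics of the training fold only; the statistics are stored
in the model and applied at prediction time, so no information leaks
from test folds through normalization.

All passes are exact analytic numpy; the test suite checks the
convolution, pooling and fully connected layers against brute-force
loop implementations (≤1e-12) and every parameter gradient against
central finite differences (relative error ≤1e-5 at h=1e-5).

## Cross-validation and metrics

Folds are stratified random splits of the epoch set: each class's
indices are shuffled with a seeded generator and dealt round-robin, so
per-class and overall fold sizes differ by at most one, every epoch is
tested exactly once, and `n = k` degenerates to singleton folds. The
splitter is intentionally not group-aware: adjacent epochs from the
same recording can land in different folds, which inflates absolute
accuracies on strongly autocorrelated signals. This protocol is
standard for segment-based evaluation and is kept here; event-based
scoring (per-seizure detection latency, false positives per hour) is
out of scope.

Binary metrics follow the confusion-table definitions with the
seizure-related state positive; a zero denominator raises an
`UndefinedMetricError` rather than returning 0, so degenerate folds
fail loudly. Fold metrics are averaged arithmetically (a pooled mode
over concatenated predictions is available via `pooled=True`). The
identity `acc = (sen·P + spe·N)/(P+N)` is property-tested on fuzzed
counts. Within one experiment, time- and frequency-domain evaluations
of a task share the fold partition so the domain comparison is paired.

## Synthetic EEG

Each state is a fixed mixture of sinusoids plus white Gaussian noise;
per channel and per timeline segment, phases are either zero or (with
`phase_randomize=True`) drawn uniformly. The default signatures
(amplitudes in µV, noise SD 5 µV) are:

| state      | oscillations                         | rationale                          |
|------------|--------------------------------------|------------------------------------|
| interictal | 10 Hz × 10, 20 Hz × 3                | alpha-dominated background         |
| preictal   | 10 Hz × 5, 15 Hz × 6, 20 Hz × 8      | power shift toward higher bands    |
| ictal      | 4 Hz × 40, 8 Hz × 15                 | high-amplitude rhythmic discharge  |

These values are this package's choices: they give each state a
distinct dominant spectral bin (4 Hz ictal, 10 Hz interictal) at an
SNR where 1-s epochs are clearly separable in the amplitude spectrum.
The simulator writes lossless CSV matrices or 16-bit EDF (round-trip
error bounded by physical range / 2¹⁶) plus a tab-separated annotation
sidecar.

What the simulator does *not* emulate: 1/f background spectra,
artifacts (eye blinks, EMG), spatial topography across channels,
nonstationarity within a state, or gradual preictal transitions.
Passing tests therefore demonstrate that the pipeline and network are
correct and that the frequency-domain advantage holds under controlled
phase variability — not that the default parameters reach any
particular accuracy on clinical recordings.

## Benchmark scale and the phase-randomization experiment

The reference experiment (`seizurecnn.benchmark`) uses 50 cycles of
[interictal 8 s, preictal 4 s, ictal 4 s] — 200 balanced epochs per
class after the margin rule — with per-segment random phases, and a
reduced optimization budget (40 SGD epochs, batch 32, learning rate
0.05) that the separable synthetic spectra do not need more of; the
architecture is untouched. Under phase randomization the amplitude
spectrum of a state is invariant across segments while its waveform is
not, so the same network on the same folds separates the states
near-perfectly in the frequency domain but imperfectly in the time
domain — the package's controlled reproduction of the
frequency-over-time finding. With phases fixed at zero instead, both
domains become easy and the contrast disappears, which is why the
benchmark randomizes them.

## Numerical and degenerate-input choices

* Pooling accumulates block elements in row-major order, making results
  bit-identical to a per-block loop.
* Constant features (zero variance in a training fold) get unit scale
  instead of dividing by zero.
* Constant channels get an artificially widened physical range in the
  EDF writer; the header's 8-character ASCII physical limits are parsed
  back and used for quantization so the 16-bit error bound holds
  despite header rounding.
* A trailing partial second of a recording is dropped; recordings with
  `fs ≠ 256` are accepted (epoch length is `fs` samples, no
  resampling).
* Training data covering fewer classes than the task raises a
  configuration error, as does a fold whose training split lost a
  class.

## Known limitations

Segment-level (not event-level) evaluation; temporal adjacency leakage
between folds inherited from the protocol; white-noise simulator; no
GPU path (the network is small enough that vectorized numpy on one CPU
trains a fold in seconds); per-patient models only, no cross-patient
pooling.
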