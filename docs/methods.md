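# Methods

## Pipeline model

`szdetect` treats seizure detection as binary image classification of
fused time-frequency representations. A record is a set of equal-length
microvolt channels at a fixed sampling rate (256 Hz throughout the
defaults, the rate of the CHB-MIT corpus) with expert seizure intervals
[t₁, t₂] in seconds. The pipeline is cross-subject: windows from all
records are pooled before shuffling and splitting, so a single classifier
is trained and tested across patients rather than per patient.

### Windowing (two steps)

*Step one — sliding segmentation.* A window of `length_s` = 180 s moves
from time 0 with fractional overlap `overlap_frac` = 0.30, i.e. stride
`length_s · (1 − overlap_frac)` = 126 s. Windows are half-open
[start, start + 180) and are dropped, never truncated, when they would
cross the record end; a window is positive iff its half-open overlap with
any seizure interval is strictly positive.

*Step two — positive augmentation.* Seizures are rare, so positives are
multiplied: starting at t₁ a window advances `step_s` = 1 s per step and
is kept while its overlap with [t₁, t₂] is at least `min_overlap_s` = 3 s
(and it fits in the record). All kept windows are positive. For an
integer-duration seizure of d ≥ 3 s this yields d − 2 windows.

The two labeling thresholds are deliberately different — step one uses
*any* positive overlap while step two enforces ≥ 3 s — because the
protocol states them separately; both are exposed as parameters.
Consecutive augmentation windows 1 s apart are near-duplicates and all
are kept; this inflates apparent test performance whenever the shuffled
split puts neighbors on both sides of the train/test boundary (see
*Limitations*).

### STFT imaging

Each window channel is transformed with a tapered short-time Fourier
transform: `win_samples` = 413 samples (≈ 1.61 s at 256 Hz), one-sided
rFFT giving ⌊413/2⌋ + 1 = 207 frequency bins, no padding and no mean
removal, so a 46080-sample window yields ⌊(46080 − 413)/hop⌋ + 1 frames.

The hop is the one genuinely underdetermined geometry parameter: a
literal 50 % overlap (hop 206 or 207) gives 221–222 frames, while the
canonical spectrogram is 207 × 224. `hop_samples` = 204 (overlap
209/413 ≈ 50.6 %) is the largest hop that produces exactly 224 frames
and is the default; it is config-overridable.

The taper is Hann (periodic) by default — standard for spectrograms, and
any scipy window name is accepted. The magnitude spectrogram is
log₁₀(|S| + eps) with eps = 1e-12 (log scaling is the default because CNN
inputs need bounded dynamic range; a linear-magnitude toggle exists),
min-max normalized per image channel to [0, 1], resized 207 × 224 →
224 × 224 bilinearly, and flipped so frequency increases from the bottom
row. The three bipolar derivations FP2-F8, F8-T8, T8-P8 map to red,
green, blue in that fixed order. Per-channel min-max normalization makes
each plane invariant to a linear gain on its signal (exactly so for
power-of-two gains, which commute with binary floating point).

### Dataset and splits

Images from all records are pooled; the split is a seeded uniform
permutation cut at 60 %/20 %/20 %, train and validation sizes rounded to
nearest and the test set taking the remainder. The shuffle is *not*
subject-stratified — that is the protocol being reproduced — so reported
test numbers are optimistic as estimates of performance on unseen
patients. `split_leave_subject_out` is provided as a stricter optional
alternative and is off by default.

### Transfer models

Every model is: frozen convolutional backbone → pooling (flatten for the
VGG family, global average for ResNet50) → FC1 → ReLU → FC2 → ReLU →
softmax(2), trained with cross entropy H(r, p) = −Σ rᵢ log pᵢ. Only the
head is trainable; `train` refuses `freeze_backbone=False` (fine-tuning
is out of scope).

Because no deep-learning framework ships with this package's
environment, the trainable parts are implemented directly in numpy
(`szdetect._nn`): Glorot-uniform initialization under the run seed,
exact backprop through the two-layer head (verified against finite
differences in the tests), SGD with the classic per-update decay
lr_t = lr₀/(1 + decay·t), and bias-corrected Adam. The
`vgg16`/`vgg19`/`resnet50` backbones are architectural descriptors
(pooled feature dimensions 25088/25088/2048 and conv parameter counts),
sufficient for building heads and auditing parameter counts; running
their feature extractors requires pretrained ImageNet weights and raises
an explicit error pointing at `tiny_random` when those are unavailable.

`tiny_random` is a first-class offline backbone: three 3×3/stride-2
conv+ReLU blocks (3→8→16→32 channels) with fixed random weights,
flattened to a 23 328-dim feature. Random convolutional features are a
legitimate frozen feature extractor for inputs whose classes differ in
coarse spectral layout, which is exactly the structure the spectrogram
images carry.

Training recipes follow the study protocol: VGG-family heads use SGD
(lr 0.001, decay 1e-5, batch 64); the ResNet50 head uses Adam (lr 0.001,
β₁ 0.9, β₂ 0.999, batch 16) with the learning rate multiplied by 0.8
after validation loss stalls for 5 epochs. All paths cap at 500 epochs,
stop early after 20 epochs without a validation-loss improvement, and
restore the parameters of the best validation epoch (best-model
restoration is standard practice; the protocol is silent on it).
Repeated evaluation (`repeat_runs`, CLI `--repeats`) re-splits, retrains
and re-tests under incremented seeds and reports per-run metrics plus
their arithmetic mean — the mean of metrics, not metrics of pooled
counts.

### Metrics

accuracy, precision, recall and the Matthews correlation coefficient are
computed exactly from TP/TN/FP/FN; any metric with a zero denominator is
defined as 0 (logged), so batch evaluation never aborts.
`confusion_from_rates` inverts a printed (accuracy, recall, precision)
triple at a given N and prevalence into real-valued counts
(TP = recall·P, FP = TP(1−precision)/precision, FN = P−TP,
TN = accuracy·N−TP) and reports the residual |ΣTP..FN − N|, which
measures how self-consistent the rounded printed rates are. Applied to
the published VGG16/VGG19 rows at N = 1695, prevalence 0.495, the
reconstruction reproduces the printed mcor values to within the
4-decimal rounding tolerance (0.9593 vs 0.9589 and 0.9656 vs 0.9653).

## Synthetic EEG generator

Each channel is `1/f^β broadband noise + background rhythm + seizure
bursts`:

| parameter | default | meaning |
|---|---|---|
| `fs` | 256 Hz | sampling rate (matches the clinical corpus) |
| `background_alpha_hz` | 10 Hz | dominant background rhythm (alpha band) |
| `background_amp_uv` | 20 µV | background rhythm amplitude, a typical scalp alpha magnitude |
| `noise_exponent` β | 1 | spectral slope of the broadband noise |
| `noise_amp_uv` | 10 µV RMS | broadband noise scale (roughly half the rhythm, keeping the rhythm dominant) |
| `seizure_freq_hz` | 5 Hz | burst rhythm, mid 3–7 Hz ictal band |
| `seizure_amp_gain` | 5 | burst amplitude = gain × background amplitude |
| `ramp_s` | 0.5 s | raised-cosine on/off ramps of the burst envelope |

Colored noise is made by shaping a white spectrum in the frequency
domain (DC bin zeroed, so the noise is exactly zero-mean) and is
deterministic under the seed. Seizure timing is shared across channels,
as on a real montage; noise and oscillation phases are independent per
channel, and inter-channel correlation is not modeled (no pipeline stage
computes across channels before fusion). The seizure is a ramped
sinusoid, not a spike-wave complex: the pipeline only requires a
time-localized spectral signature, and a sinusoid keeps the band-power
test oracles closed-form (gain 5 on the added component implies an
inside/outside 3–7 Hz band-power ratio well above 4, which the tests
check with an independent Welch periodogram).

**What passing on this generator shows — and does not.** It validates
the mechanics end to end: windowing counts and labels, spectrogram
geometry and normalization, split bookkeeping, optimization, stopping
rules and metric arithmetic. It does not show clinical performance: real
ictal EEG has evolving morphology, artifacts (muscle, eye, electrode),
inter-subject spectral variability and far lower contrast than a gain-5
sinusoidal burst. The near-perfect synthetic accuracies are a property
of the generator's strong class separation, not a clinical claim.

## Numerical choices and degenerate inputs

- Window-fit comparisons use a 1e-9 s tolerance so sample-grid rounding
  of record durations cannot drop a boundary window.
- A spectrogram plane that is constant (e.g. an all-zero signal)
  min-max-normalizes to all zeros rather than dividing by zero.
- EDF writing (fixtures and `simulate` output only) quantizes to 16 bits
  with the physical range taken per channel from the signal min/max; the
  range is first rounded to EDF's 8-character header fields so that
  write→read round-trips to within one quantization step. Reading goes
  through `mne`; requested bipolar labels prefer a stored bipolar
  channel and fall back to subtracting the two referential channels.
- Annotation times are parsed as printed (integer seconds in the
  CHB-MIT dialect) but held as float seconds internally.
- Records shorter than one window yield an empty segment list with a
  warning; a seizure shorter than the 3 s overlap rule yields zero
  augmentation windows.
- Splits are seeded `numpy` permutations; every stochastic stage
  (generator, initialization, shuffling) is deterministic given its
  seed, so identical configs reproduce identical artifacts bitwise.

## Problem sizes used in the tests

The test suite and the desk-scale learning check run on synthetic data
sized for a single CPU: the end-to-end check trains the `tiny_random`
backbone with a 128×64 head on 400 balanced images (one 180 s window per
record) and requires ≥ 0.95 held-out accuracy; oracle comparisons use
50–1000 random parameterizations per property. These sizes are the
package's own choices for fast, deterministic verification.

## Known limitations

- Pretrained VGG/ResNet feature extraction is declared but not runnable
  without ImageNet weights; all runnable training uses `tiny_random`.
- The pooled shuffle leaks subjects and near-duplicate augmentation
  windows across partitions; use `split_leave_subject_out` for honest
  generalization estimates.
- No denoising or artifact handling is applied to input EEG.
- Multi-class staging (pre-ictal/ictal/post-ictal), event-latency
  metrics and ROC analysis are out of scope.
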