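# Methods

This note records the models, conventions and numerical choices behind
`drilldetect`, in the spirit of a package's methods documentation: what
is computed, under which assumptions, and what a green test does and
does not establish.

## 1. Detection task and protocol

The detector classifies each sliding analysis window of structure-borne
drill audio as *cortical* (drilling dense bone) or *breakthrough* (the
bit perforating into soft tissue). The window length `L` bounds the
reaction latency — the audio must exist before it can be classified —
so three short windows are supported: 100, 50 and 25 ms at 44.1 kHz
(`L = 4410, 2205, 1102` samples). Deployment slides the window in steps
of `⌊L/4⌋` (75 % overlap, matching the training framing).

A window inherits the *breakthrough* label when its overlap with an
annotated event interval reaches `min_overlap_ms` (default: half the
window, 50 ms for 100 ms windows, scaled proportionally). Ground-truth
annotation labels whole cut segments; the overlap rule is the package's
deterministic extension of those cuts to a window grid. Windows with
50–99 % event overlap are genuinely mixed; they enter training with the
breakthrough label so the decision boundary sees them.

## 2. Features

For each analysis window:

1. **Centered STFT.** The window is zero-padded by `N/2` samples on
   both ends (`N = 2048`), cut into Hann frames
   `w(n) = ½(1 − cos(2πn/(N−1)))` of length `N` at hop `H`, and each
   frame is Fourier transformed. This centering is the one framing
   convention under which the number of time frames is exactly
   `1 + ⌊L/H⌋ = 69` for all three `(L, H)` pairs, keeping the network
   input shape constant at 256×69.
2. **Power and decibels.** Squared magnitudes, floored at `1e-10`
   before `10·log10` so silence maps to −100 dB instead of −∞.
3. **Mel filterbank.** 256 triangular filters whose peaks are evenly
   spaced on the mel axis (`f_mel = 2595·log10(1 + f/700)`, HTK
   constants) between 0 and 22.05 kHz, applied to the *power*
   spectrogram before the log. With 256 bands against a 21.5 Hz FFT bin
   spacing, the lowest triangles are narrower than one bin; a filter
   whose sampled weights would all vanish receives unit weight at the
   bin nearest its peak, so every row is non-negative with a single
   maximum and no information is silently dropped. `N = 2048` was
   chosen as the smallest power of two giving at least `2·n_mels`
   frequency bins.
4. **Normalization.** Scalar `μ` and `σ` over *all entries of all
   training spectrograms* (the defining formula uses unsubscripted
   scalars, i.e. global rather than per-bin statistics), fitted per
   cross-validation fold on that fold's training pool only and applied
   unchanged to held-out data.

A useful exact property used in tests: scaling the waveform by `g`
shifts every log-mel entry by `20·log10(g)` dB (away from the floor).

## 3. Classifier and loss

The trunk is a post-activation ResNet-18 adapted to one input channel:
7×7/stride-2 stem convolution, 3×3/stride-2 max pooling, four stages of
two basic blocks (two 3×3 bias-free convolutions, each followed by
batch normalization; identity shortcuts, or 1×1-projection + BN where
shape changes), widths 64/128/256/512, closed by a final batch
normalization. The head is global average pooling → dropout 0.5 → dense
1024 (ReLU) → dropout 0.5 → dense 1 with sigmoid. The second dropout
rate is unspecified upstream and set equal to the first; the dense-1024
activation is likewise unstated and set to ReLU.

Counting weights, biases, batch-norm affine parameters and running
statistics gives 11,708,225 parameters — within 0.1 % of the published
11,715,393, which no standard counting convention reproduces exactly;
the package therefore treats the printed figure as a ±0.5 % consistency
band.

Training minimizes the focal loss

    FL(p_t) = −α_t (1 − p_t)^γ ln(p_t),   p_t = p if y = 1 else 1 − p

with `α_t = 0.25`, `γ = 2`, probabilities clamped to `[1e-7, 1 − 1e-7]`.
`α_t` is applied *uniformly* to both classes, exactly as the defining
formula is written — at `γ = 0`, `α_t = 1` the loss reduces to binary
cross-entropy to machine precision, which the tests assert. The natural
logarithm is used (standard for this loss; the source writes "log"
without base). Optimization is Adam (lr 1e-3, default moments), with
the learning rate multiplied by 0.1 whenever the monitored validation
loss fails to improve by `1e-4` for three consecutive epochs;
best-validation-loss weights are restored at the end.

Because no deep-learning framework is available in the target
environment, convolution (im2col), batch normalization, pooling, dense
layers, dropout, backpropagation and Adam are implemented directly on
numpy in float32. Gradients are verified against central differences in
the test suite.

## 4. Class balancing

Breakthrough material is outnumbered by more than an order of
magnitude. Training folds are balanced by expanding breakthrough clips
with singly-applied variants — gains of −5/+5 dB, phase-vocoder time
stretches of 0.5/0.7/1.2/1.5× (duration scales as 1/rate, pitch
preserved), and pitch shifts of −3/−1/+1/+3 semitones (time-stretch
then resample; duration preserved) — ten variants per clip per pass.
Passes repeat on the newest generation, with seeded subsampling on the
final pass, until the majority:minority ratio (measured in analysis
windows, since stretching changes how many windows a clip yields)
reaches the target of 1.0. Whether the original study generated all
variants or sampled a subset is not stated; repeated passes with a
subsampled final pass is this package's choice. The majority class is
never touched, augmentation happens after the fold split and before
feature extraction (variants are re-windowed), and augmented clips
carry a provenance flag so leakage into held-out splits is checkable.

## 5. Cross-validation

Folds are grouped by `source_id` (drill hole): per-window splits would
place near-duplicate overlapping windows of the same hole on both sides
of the split and inflate scores. Each group lands in exactly one fold;
fold sizes are balanced within one group. Within a fold, the training
split provides normalization statistics and augmented clips; the
held-out fold is scored on the full `⌊L/4⌋` sliding grid and also
serves as the monitored validation set for best-weight selection and
the LR schedule (the upstream protocol reports only train/test phases;
no inner validation split is described). Reported metrics: per-fold
2×2 confusion matrices, per-class sensitivity (recall) mean ± std —
breakthrough sensitivity being the primary metric — and train/test
accuracy side by side.

Training windows use the same overlap-labeled grid as evaluation, with
one concession to the single-CPU budget: cortical training windows are
decimated 4× to a non-overlapping grid (overlapping windows of a
stationary texture are near-duplicates and add cost, not information).
Held-out scoring always uses the full grid.

## 6. Synthetic data generator

The generator emulates the qualitative structure of structure-borne
recordings of drilling through the far cortical layer until
breakthrough; the real recordings are not deposited, so the model is a
stated world, not a fit:

- **Cortical texture** — a harmonic stack at a drill fundamental of
  650 Hz (high-speed drill motor/gear vibration; 10 harmonics with 1/k
  amplitudes), slow ±2 % random-walk frequency jitter, 10 % amplitude
  modulation at ~3 Hz, plus broadband noise 10 dB below the harmonics,
  low-pass filtered at 6 kHz to mimic soft-tissue damping.
- **Breakthrough** — at the end of each recording (one event per drill
  hole, as one hole yields one perforation): the harmonic envelope
  collapses to 15 % within ~10 ms (cutting resistance gone) while a
  broadband burst (5 ms attack, bandwidth 2.5× the cortical cutoff,
  ~3× the cortical RMS) rings for a duration drawn uniformly from
  100–250 ms.
- **Bookkeeping** — recordings are 3 s by default, giving a worst-case
  cortical:breakthrough ratio of 11 (> 10, i.e. more than an order of
  magnitude); samples are peak-normalized to 0.9; synthesis is
  deterministic float64 first, 24-bit quantization last (no dither);
  identical `(config, seed)` give bit-identical corpora.

The defaults are fixed once: fundamental, harmonic count, SNR and
cutoff are plausible for a battery drill sensed through tissue but are
*not* validated against cadaver data (none is available). The simulator
also does not model: drill-speed drift under load, inter-specimen
variability, electromagnetic interference, sensor placement differences
(the `position` tag only separates datasets), or ambiguous labels near
the perforation onset. A green parameter-recovery test therefore
establishes that the pipeline — labeling, balancing, features,
training, grouped evaluation — recovers a detectable class structure;
it does not certify cadaver-level sensitivities. The published headline
numbers (93.64 ± 2.42 % breakthrough sensitivity at 100 ms, etc.)
appear here as context only.

A spectral-contrast property is asserted in tests: the mean log-mel
distance between breakthrough and cortical windows exceeds the mean
within-class distance, i.e. the synthetic learning problem is solvable
by construction.

## 7. Latency model

The end-to-end delay is an exact sum of four non-negative components:
driver latency (default 6.8 ms, the measured ASIO constant of the
reference interface; configurable, as it is hardware-specific), window
acquisition `1000·L/44100` ms (100/50/≈25 ms), and measured feature and
inference times. The measured components are reported per streaming
event but never asserted in tests — they are hardware-dependent.
`L = 1102` gives 24.9886… ms, i.e. 25 ms at the integer precision
budgets are printed with.

## 8. Desk-scale profiles

The full 11.7M-parameter network trains impractically slowly on one CPU
in numpy, and nothing about the pipeline's correctness depends on trunk
width. `ModelSpec.reduced()` (blocks [1,1,1,1], widths [4,8,16,32],
64-unit head) and `TrainingConfig.reduced()` (4 epochs — validation
loss on the synthetic corpus converges within the first epochs) exist
for tests, CLI defaults and synthetic-corpus experiments; the full
architecture remains the default `ModelSpec()` and is what the
parameter-count checks build.

## 9. Numerical conventions and degenerate inputs

- STFT padding is zero-valued (not reflective); the Hann window uses
  the symmetric `N − 1` denominator.
- Analysis-window step is `⌊(1 − overlap)·L⌋` (4410 → 1102), an
  integer grid; the trailing partial window is dropped.
- dB floor `1e-10` on power; probability clamp `1e-7`; batch-norm eps
  `1e-5`, momentum 0.1, biased batch variance.
- Constant training features (σ = 0) raise rather than divide by zero;
  clips shorter than one window yield an empty result with a warning;
  empty corpora, inverted intervals, mismatched sample rates and
  invalid `(L, H)` pairings raise configuration errors listing the
  valid options.
- 24-bit WAV write rounds to the nearest code after clipping to
  `[−1, 1 − 2⁻²³]`; round-trip error is below `2⁻²⁴` per sample.
  Reading maps integer PCM onto `[−1, 1]` by the type's full scale.

## 10. Known limitations

- The simulator's realism is unvalidated (see §6); results on it bound
  pipeline correctness, not clinical performance.
- Only singly-applied augmentation variants are generated; composed
  transforms (e.g. gain + stretch) are not.
- The streaming module processes arrays/files; real audio-driver
  capture is out of scope and enters only as the constant driver
  latency.
- Decision threshold is fixed at 0.5; threshold sweeps, event
  debouncing across consecutive windows, and drill-stopping actuation
  are out of scope.
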