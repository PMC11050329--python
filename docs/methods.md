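# Methods

This note documents the models and procedures implemented in `rmamnet`:
what is computed, which knobs matter, what the synthetic corpus does and
does not emulate, and where genuinely open design choices were resolved.

## Problem setting

Wood-boring larvae (the emerald ash borer, EAB, and the carpenter moth
*Holcocerus insularis*) feed on the cambium inside tree trunks.  A
piezoelectric probe embedded in the trunk records the substrate-borne
feeding vibrations as mono 16-bit audio.  The classification task has four
classes: (0) EAB-like feeding pulses, (1) *H. insularis*-like pulses,
(2) a 1:1 computer overlay of both — the case where both species infest
one tree — and (3) ambient noise.

## Synthetic corpus generator

No public recording corpus exists, so the package ships a first-class
generator that reproduces the documented phenomenology of feeding
vibrations: trains of discrete, sharp pulses with a fast attack and
gradual decay, irregular inter-pulse intervals, and species-distinct
spectral bands.

Model, per species profile:

* **Pulse**: a carrier (sine or sawtooth, frequency drawn uniformly from
  the middle half of the species band, then 4th-order Butterworth
  band-pass filtered to the band) multiplied by an envelope with a
  raised-cosine rise over `attack_ms` and exponential decay with time
  constant `decay_ms`.  Defaults: attack 1.5–2 ms, decay 12–18 ms.
* **Pulse train**: onsets follow a homogeneous Poisson process
  (`pulse_rate_hz`, defaults 8 and 5 /s), matching "irregular intervals"
  with a single parameter.  Peak amplitudes are log-normal with mean
  0.5 full scale and coefficient of variation 0.3.
* **Background**: white Gaussian noise whose standard deviation is set
  `snr_db` (default 10 dB) below the nominal pulse peak.
* **Gain**: constant across recordings, with samples hard-clipped at
  ±1 like an ADC.  An earlier revision peak-normalised each recording by
  its own maximum; that injects a random per-recording gain (an automatic
  gain control no fixed-gain sensor chain has) and, because absolute level
  is the main cue separating a single species from the half-amplitude 1:1
  mix, it destroyed generalisation across recordings.  Fixed-gain synthesis
  is both the realistic and the learnable choice.
* **Mixing** (class 2): sample-wise `(a + b) / 2` of freshly synthesised
  class-0 and class-1 material (never files assigned to classes 0/1), with
  peak renormalisation only if the result leaves [−1, 1].
* **Band placement**: real EAB energy concentrates near 17.5 kHz and
  *H. insularis* near 10 kHz at 44.1 kHz capture, but the standard
  preprocessing resamples to 16 kHz (Nyquist 8 kHz), which would discard
  both bands.  Default profiles therefore sit at 3.5 kHz and 6 kHz so the
  16 kHz pipeline retains the discriminative structure;
  `native_rate_profiles()` restores the literal band centres for users who
  keep the native rate.
* **Corpus composition**: each signal class contributes
  `minutes_per_class` of audio; the noise class contributes 1.2× that,
  mirroring the published corpus composition (250 min per signal class,
  298 min of noise).  Recordings are organised into simulated days with
  first/middle/last thirds so the temporal split has its metadata.

What the generator does **not** emulate: wood propagation physics and
resonances, sensor transfer functions, non-stationary field noise
(wind, rain, machinery), diurnal activity rhythms, or amplitude decay
with larva–sensor distance.  Passing tests therefore demonstrate that the
pipeline and network learn spectro-temporal pulse structure under
controlled conditions — not field-grade performance.

Pulse rates, amplitudes and SNR of real larvae are not quantified
anywhere in the source material; the defaults above are plausible for
clearly audible feeding activity and are fixed, not calibrated.

## Dataset construction

Recordings are cut into consecutive, non-overlapping 5-s segments (the
trailing remainder is discarded; overlap would leak correlated content
between splits).  Each day's material is divided into first/middle/last
30-minute thirds: training segments may only come from first/middle
thirds, test segments only from last thirds.  Within those pools a seeded
random selection enforces a 5:1 train:test count ratio per class
(`k = min(⌊train_pool/5⌋, test_pool)`; `5k` train and `k` test segments
drawn without replacement).  A leakage assertion on
(recording, offset) pairs runs on every build.

## Feature extraction

Per segment: resample to 16 kHz (polyphase); crop or zero-pad to exactly
3 s — random offset for training (augmentation), centre crop for
evaluation (deterministic); pre-emphasis `y[n] = x[n] − 0.97·x[n−1]`
(coefficient unstated in the source, 0.97 is the standard speech default);
frame with a 512-sample Hanning window at hop 160, reflect-padded by half
a window so the frame count is `1 + ⌊48000/160⌋ = 301`; squared-magnitude
FFT; 80 triangular HTK-Mel filters (2595·log10(1+f/700), 0 Hz–Nyquist,
peak height 1); natural log with a 1e-10 floor for silent frames.

Output: an 80 × 301 matrix.  The 80 Mel bands act as the network's input
channels and the 301 frames as its length.  Without centred framing the
count would be 297, so centring is required to reproduce the published
feature size.  An off-by-default `apply_dct` flag applies an orthonormal
type-II DCT along the Mel axis for users who want cepstral coefficients;
the default output is the log-Mel spectrogram, which is what the network
input size and all downstream shapes assume.

## Network

The residual mixed-domain attention module (RMAM) computes, for input x:

    M  = ConvModule2(ConvModule1(x))          ConvModule = conv1d + BN + sigmoid
    Nz = M ⊗ ẑ     ẑ = σ(W2 ReLU(W1 z)),  z = per-channel mean over time
    Nt = M ⊗ q̂     q̂ = σ(w2 ReLU(w1 q)),  q = 1×1 conv collapsing channels
    y  = (Nz + Nt) + skip(x)

Channel attention is a squeeze-excitation-style bottleneck
(C → C/r → C, r = 4 by default; width floors at 1 with a logged note when
C is not divisible by r).  Time attention collapses channels with a 1×1
convolution and maps the length-L descriptor through two position-shared
1×1 layers.  Both weight vectors pass through a sigmoid, so every weight
lies strictly in (0, 1) and both branches are pure elementwise
reweightings — they never change tensor shape.

How the two branches combine is unstated in the source; elementwise sum
is the default (mean is available) because it preserves shape and is
standard in mixed-attention blocks.  The residual skip uses a 1×1
projection when channel counts change.  Activations inside the conv
modules are sigmoid by fidelity to the described architecture, with a
ReLU switch for ablation.

The default 10-learnable-layer stack on an 80 × 301 input:

    RMAM(k=12, 128) → maxpool 4 → RMAM(k=6, 256) → maxpool 4
    → RMAM(k=3, 256) → maxpool 2 → RMAM(k=3, 256) → maxpool 2
    → conv(k=3, 256)+BN+σ → maxpool 2 → GAP → FC softmax(4)

Spatial lengths are recomputed from kernels/strides
(301 → 75 → 18 → 9 → 4 → 2) rather than copied from any table; the
channel progression 80 → 128 → 256 → 256 → 256 → 256 and the 256-wide
global-average-pooled feature vector are the architectural invariants
later stages depend on.

## Training and evaluation

The network trains with Adam (1e-3) on mean cross-entropy over shuffled
mini-batches; optimiser, learning rate and loss are unstated in the
source, and these are the standard choices at this scale.  The reference
run used batch 512 for 12 epochs on ~10k field segments; the desk default
batch is 32 so small synthetic corpora still produce several updates per
epoch.  Batch norm uses batch statistics in training and exponential
running averages (momentum 0.1) in evaluation.  A learning rate of 0 is a
strict no-op: parameters *and* running statistics stay frozen.  NaN loss
aborts with a learning-rate hint.  No validation split is carved out by
default.

Evaluation reports accuracy (percent), macro F1 (the unweighted mean of
per-class F1, matching the per-class confusion presentation; the F1
variant is unstated in the source), per-class precision/recall/F1, and
the 4×4 confusion matrix.  A class absent from the test set gets F1 = 0
with a warning.  Metrics are segment-level; file-level aggregation can be
done by majority vote over a recording's segments but is not the default.
`embed_2d` applies seeded t-SNE to the 256-dim GAP features, with
perplexity auto-reduced for small N.

## Numerical choices

* All network arithmetic is float32; gradients are verified against
  central finite differences in the test suite.
* Sigmoid saturation at ±500 is exact 1/0 in float32 — used by tests to
  pin attention weights.
* Log floor 1e-10 before the logarithm; BN epsilon 1e-5.
* Glorot-uniform initialisation (sigmoid-friendly).
* Max-pooling drops a trailing remainder shorter than the pool window.
* Batches with fewer than 2 samples are skipped (batch statistics are
  undefined for a single sample).

## Study-scale end-to-end run

`study_corpus_config()` fixes the synthetic study conditions: 18 minutes
per signal class (~216 five-second segments each; the noise class 1.2×
more), which the 5:1 temporal split turns into ~590 training and ~120
test segments.  Training for 8 epochs at batch 32 takes minutes on one
CPU core.  Under these conditions the four classes are separable by
construction — a logistic regression on per-band mean energies, used as
an independent oracle, classifies the same test set at ≳95% — so the
network is expected to reach ≥90% test accuracy, far above the 25%
chance level.  `scripts/acceptance.py` recomputes all of this from
scratch.

## Known limitations

* The network is implemented on an in-package numpy autodiff engine;
  it is CPU-only and has no GPU path, so the reference batch size of 512
  is impractical though configurable.
* Checkpoint resume restarts Adam's moment estimates (the epoch counter
  and weights persist).
* The synthetic corpus is stationary and spectrally clean; headline
  field-data accuracies cannot be reproduced or refuted with it.
* t-SNE coordinates are only comparable within one run/seed.
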