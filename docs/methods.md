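# Methods

`eegart` implements a dual-branch neural classifier for single-channel EEG
artifact segments, together with the signal-conditioning pipeline that
produces those segments from raw recordings and a synthetic generator that
makes the whole stack testable without clinical data.  This note documents
the model, the processing choices, the synthetic data, and the numerical
decisions a user should know about.

## The classification model

The input is one segment x(n), `segment_seconds * fs` samples of a single
bipolar EEG channel (4 s at 250 Hz = 1000 samples in the reference
configuration), optionally z-scored per segment.  Two branches process it
in parallel.

**Time branch.**  A two-layer 1-D convolution stack extracts shallow local
features: Conv(1→16, kernel 8, stride 4) → BatchNorm → ELU →
MaxPool(4, stride 2) → Conv(16→40, kernel 4, stride 2) → BatchNorm → ELU →
MaxPool(2, stride 1).  The first, wider kernel covers a longer temporal
range; the second focuses on rapid local changes.  The output is read as a
sequence of T tokens of width n = 40 (T = 59 for 4 s input).  A 6-layer
transformer encoder with 5 attention heads (d_model 40, per-head width
d_k = 40/5 = 8, scaled dot-product attention softmax(QKᵀ/√d_k)V) produces
global features of the same shape.  A further Conv(40→40, kernel 3) over
the encoder output extracts *deep local* features (T₁ = T − 2 tokens):
local refinement of globally contextualised features.

**Time-frequency branch.**  The segment is converted to a one-sided
magnitude STFT with a Hamming window of 250 samples and 200 samples
overlap (hop 50), giving 126 frequency bins × 16 frames for 4 s input, with
log(1 + m) compression.  A 2-D convolution stack (Conv(1→16, (1,3)) → BN →
ELU → MaxPool(2,2) → Conv(16→40, (3,1)) → BN → ELU → MaxPool(2,2), all
stride 1, no padding) yields a 40 × 122 × 12 feature map, flattened
row-major into a sequence of 122·12 = 1464 tokens.  A second transformer
encoder (same shape, separate weights) produces global features; a
Conv(40→40, (3,3)) applied after unflattening gives the deep local
features, T₂ = 120·10 = 1200 tokens.

**Fusion.**  Within each domain the shallow, global and deep sequences are
concatenated along the token axis and mixed across channels by a
kernel-1 convolution (length preserved: T₃ = 2T + T₁ = 175 and
T₄ = 2·1464 + 1200 = 4128).  The two domain feature sets are concatenated,
time domain first (4303 × 40 total), flattened, and classified by
FC(→128) → ELU → Dropout(0.5) → FC(→m) → softmax.  Training minimises mean
cross-entropy with Adam (lr 2·10⁻⁴, β₁ 0.9, β₂ 0.999).

**Ablation variants** prune stages cumulatively: `cnn` (time conv stack →
classifier), `cnn_tf` (+ encoder), `cnn_tf_fusion` (+ shallow/global
concatenation), `cnn_tf_cnn_fusion` (+ deep local features and kernel-1
fusion, time domain only), `full` (both domains).  Parameter sets are
nested along this order.  **Fusion strategies**: `concat_cnn` (the
default, above), `weighted` (each feature group mean-pooled to one
n-vector, a shared two-layer MLP scores the groups, softmax weights,
weighted sum), and `weighted_cnn` (the three weighted vectors kept as a
length-3 sequence and mixed by a kernel-1 convolution).

### Pinned hyperparameters the architecture leaves open

Several widths are not determined by the architecture's published
description; this implementation pins them as follows and treats them as
part of the reference configuration:

- attention scale: d_k = d_model / heads = 8 (the conventional per-head
  key width; an alternative reading that sets d_k to the sequence length
  would make the scale depend on input length, which contradicts the
  standard attention formulation);
- encoder feed-forward width 4 × d_model = 160; pre-norm layer order with
  a closing LayerNorm; no positional encoding by default (sinusoidal
  available via `TransformerConfig.positional_encoding`);
- deep-local convolutions 40→40, kernels 3 and (3,3), stride 1, no
  padding, each followed by BatchNorm + ELU;
- classifier hidden width 128, dropout 0.5;
- the 2-D stack applies the (1,3) kernel first and (3,1) second; the
  transposed order is available (`table_kernel_order=False`) and yields
  identical output dimensions;
- weight init: fan-in-scaled uniform U(±1/√fan_in), biases zero (so a
  zero input yields exactly uniform class probabilities at
  initialisation); argmax ties break toward the lowest class index.

With these choices the 4 s reference model holds ≈ 22.3 M trainable
parameters, dominated by the first classifier layer (4303·40 → 128); the
count grows monotonically with segment length (2 s ≈ 7.5 M, 5 s ≈ 29 M by
construction of the flattened width).

### Short-segment rule

For 1 s segments the spectrogram has a single frame, so the 2-D stack
cannot apply width-3 kernels unpadded.  When a configuration produces
fewer than 5 frames, 2-D convolutions switch to "same" zero padding along
the time axis only, and pooling kernels clamp to the available extent.
The canonical 4 s configuration (16 frames) uses no padding anywhere.

## Preprocessing

Order is fixed: rational resampling to 250 Hz → 0.5–80 Hz band-pass →
50 Hz notch → annotation-driven extraction → non-overlapping windowing.

- **Resampling** 256 → 250 Hz uses polyphase filtering with up/down
  factors 125/128 (`scipy.signal.resample_poly`).  The Kaiser-windowed
  anti-aliasing FIR (β = 14, ≈ 100 dB stopband, passband flat to < 10⁻⁶)
  cuts at the 125 Hz target Nyquist, serving as both the pre-low-pass and
  the interpolation filter.  Other input rates use the reduced fraction
  250/fs.
- **Band-pass**: Butterworth order 4 applied forward–backward
  (`sosfiltfilt`, effective order 8, zero phase).  Zero-phase filtering
  preserves waveform morphology, which matters for transient artifacts.
- **Notch**: second-order IIR at 50 Hz, quality factor 30, zero-phase.
- **Extraction** uses half-open sample spans [⌊start·fs⌋, ⌊stop·fs⌋) per
  annotated channel; intervals shorter than `min_seconds` (default 4 s)
  are dropped, annotations on missing channels are skipped with a logged
  warning.
- **Windowing** takes consecutive non-overlapping `segment_seconds`
  windows from each span and drops the remainder.  Per-segment z-scoring
  (SD guarded at 10⁻⁸) is on by default: raw microvolt scales vary by
  orders of magnitude across artifact types and destabilise training.
- Channel restriction defaults to off; the frontal/fronto-temporal set
  FP1-F7, FP2-F8, FP1-F3, FP2-F4 (where automatism artifacts appear) is
  available via `PreprocessConfig.leads`.

## Synthetic data

The generator produces class-conditional waveforms over a 1/f (pink)
background with an 8–12 Hz alpha component (default 30 % relative power),
standardized to unit variance and scaled to 15 µV RMS.  Artifacts are
added at a target SNR (artifact power / background power, default 10 dB):

| class | waveform | default rate |
|-------|----------|--------------|
| EYEM  | 0.5–1 s half-sine deflections, alternating polarity | 0.75 Hz |
| BLINK | stereotyped biphasic 0.2–0.4 s transients | 2 Hz |
| CHEW  | 20–60 Hz EMG bursts (0.25 s), onsets jittered ±30 % of the interval | 1.5 Hz |
| RC    | the same bursts, strictly periodic | 2 Hz |
| MUSC  | sustained 20–80 Hz band-limited noise | — |
| ELEC  | step with slow exponential return, impulsive pops, or flat-line dropout (subtype uniform at random) | — |
| SHIV  | 9–11 Hz sinusoidal bursts (0.5 s) | 1 Hz |

The ±30 % jitter vs. zero jitter operationalises the distinction between
ordinary and rhythmic (automatism) chewing.  Amplitudes are nominal
microvolts (EYEM/BLINK 150, CHEW/RC/MUSC 80, ELEC 300, SHIV 60) but are
rescaled when an SNR is requested.  Per-segment seeds are derived from
(master seed, class, index), so any subset of a dataset regenerates
bit-identically regardless of what else is requested.

What the generator does **not** emulate: multi-channel spatial structure,
non-stationary background (sleep stages, drowsiness), real artifact
amplitude distributions, co-occurring artifacts, or any seizure activity.
Passing tests on this data shows the pipeline is correct and the
architecture can learn spectro-temporally separable classes; it says
nothing quantitative about clinical performance.

## Training protocol

Stratified 5-fold cross-validation; each fold trains on 4/5 of the data
and tests on 1/5 (an 8:2 split per fold — the single protocol consistent
with both stated ratios).  Default Adam settings as above, batch size 200,
up to 100 epochs with early stopping (patience 10) on a stratified 10 %
validation slice of the training split; the best-validation weights are
restored.  Per-class metrics are one-vs-rest from the multi-class
confusion matrix: accuracy (TP+TN)/total, recall TP/(TP+FN),
F1 2TP/(2TP+FP+FN), with zero denominators reported as 0 with a warning;
"macro" values are unweighted class means.  All randomness (init,
shuffling, dropout) derives from explicit seeds; training is bit-
reproducible on a given machine in the default deterministic mode.

## Problem sizes in the shipped tests and acceptance script

The network and training loop are pure numpy (with a small reverse-mode
autodiff tape under `eegart.nn`); a training pass over one 4 s segment
costs roughly one CPU-second because the time-frequency branch runs
6 layers of full self-attention over 1464 tokens.  The shipped end-to-end
experiments therefore use a small problem: 6 classes × 12 segments,
5-fold CV, 2 epochs, batch 4, fixed seeds.  At this size the experiment
exercises every stage (generation, STFT, both branches, fusion, Adam, CV,
metrics) and is fully deterministic, but it sits far below the data and
step budget the full model needs to converge: measured at this scale the
full model reaches ≈ 0.7 mean CV accuracy, and whether it overtakes the
conv-only variant varies with the seed, whereas the band-power rule in
`tests/oracles.py`
certifies the classes are ≥ 90 % separable, and the conv variant fits
trivially separable two-class tone data to 100 % training accuracy within
a few epochs.  Scaling the same protocol up (hundreds of segments per
class, tens of epochs) is a matter of CPU hours, not code changes.

## Numerical notes

- Everything trains in float32; gradient-check tests run the same ops in
  float64 against central differences.
- Self-attention keeps its (T × T) weight matrices in reusable scratch
  buffers; with large sequences the weights are recomputed head-by-head
  during backpropagation (or cached when a 400 MB/layer budget allows),
  bounding peak memory at a few GB for the 1464-token branch.
- Softmax and cross-entropy use max-subtraction; probabilities are
  clamped at 10⁻¹² inside the loss.
- BatchNorm uses batch statistics in training and running averages
  (momentum 0.1) at inference; a freshly initialised network in inference
  mode maps zero input to exactly uniform probabilities.
- Degenerate inputs: zero-variance windows z-score to zero (guarded SD);
  empty evaluation masks, starved CV classes, non-finite losses, and
  shape mismatches raise immediately with named stages.

## Known limitations

- Single-channel only; no spatial modeling.
- The quadratic cost of full attention over 1464 spectrogram tokens
  dominates runtime; training the reference configuration at realistic
  dataset sizes wants a GPU-backed tensor library, which this
  implementation deliberately does not depend on.
- The synthetic task is easier than clinical data (stationary background,
  one artifact per segment, exact class balance).
- EDF writing supports integer sampling rates and 16-bit range scaling
  per channel; reading relies on mne and inherits its handling of
  mixed-rate files (resampling to the highest rate, with a warning).
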