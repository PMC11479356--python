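# Methods

This note documents the models, conventions and design choices behind
`adlsound`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data does and does not show.

## Signal model and capture

Audio is mono 16 kHz float32 in [−1, 1]; the hardware delivery unit is a
512-sample buffer (32 ms), and everything downstream works at that
granularity. Capture gating uses the mean absolute amplitude of a buffer,
`E = (Σ|xₙ|)/512`, not RMS — it is the cheaper statistic an always-on
low-power core would compute. A segment opens at the first buffer with
`E ≥ wake_threshold` (default 0.01 full-scale; the deployed trigger level is
hardware-specific, so this is a config key, `capture.wake_threshold`) and
closes after `stop_silence_s` (default 5 s ⇒ 157 consecutive quiet buffers);
one loud buffer resets the silence counter. Trailing silence is trimmed from
the emitted segment; a partial final buffer is dropped, mirroring
buffer-granularity hardware. Consequences: raising the threshold can only
reduce the segment count, and re-gating a gated segment is a no-op.

## Streaming features

The extractor avoids an analysis window entirely: each buffer is
concatenated with its predecessor into a 1024-sample rectangular frame, so
the hop equals the buffer size (50% overlap) and the DFT can run
incrementally during reception. For a 1 s input this produces exactly 32
frames: the first frame uses 512 zeros of prehistory (the stream has no
past at t = 0) and the final quarter-buffer is zero-padded. The 512
frequency bins are k = 0…511 of the one-sided 1024-point spectrum — the
Nyquist bin is dropped; the topmost mel filter's weight at exactly 8 kHz is
zero, so nothing is lost. Power (|X|²) is used throughout.

The mel stage uses the HTK mapping `m = 2595·log₁₀(1 + f/700)` with 48
triangular filters equally spaced on the mel scale over 0–8 kHz and
area-normalized (each triangle scaled by 2/bandwidth). 48 bands rather than
the speech-standard 40: household noise carries information across the full
band, and 48 = 2×24 matches the model's pooling geometry. The log transform
is decibel (10·log₁₀), referenced to the matrix maximum and floored 80 dB
below it — this also makes features invariant to overall recording gain,
which is why synthetic clips at different levels classify identically. The
whole pipeline is cross-checked in the tests against an independently coded
direct-DFT + triangle-filter + dB oracle at 1e-4 elementwise.

Feature quantization is affine int8, `q = clamp(round(x/s) + z, −128, 127)`,
with (s, z) calibrated globally on the training features (fixed-scale
deployment, not per-clip). The calibration range is nudged to include zero —
the usual deployment convention, and required for the zero point to be
representable; for dB features referenced to max (range ⊆ [−80, 0]) the
nudge is a no-op. Payload: 48·32·4 = 6144 B/s float, 1536 B/s int8.

## Synthetic data: what it emulates, what it does not

Recorded in-home audio for this problem cannot be redistributed, so the
package ships a parametric generator for the 11 activity sound labels plus
`background`. Recipes are chosen so that each label has a stable spectral
fingerprint of the right *kind*: band-limited noise with distinct passbands
for the two water classes; ~4 Hz amplitude-modulated noise for brushing;
crackle-over-hiss for cooking; 60 Hz and 50 Hz harmonic stacks with fan
noise (different weights) for microwave and ventilation; syllabically gated
formant stacks for speech, with added music-band energy for TV; a narrow
trickle band for peeing; a ≤ 0.3 s exponentially decaying broadband burst
for hitting; a rise–sustain–fall gurgling low-band rush (~10 Hz
modulation) for flushing; low-level pink noise for background. Continuous
textures get 150 ms raised-cosine edge fades — physical sounds do not stop
in one sample, and an unfaded step edge reads as an impact transient.

Training pools add a pink-noise bed at 15–25 dB SNR per clip, and 20% of
continuous-texture clips carry the sound over only 0.4–0.9 s of the window:
one-second segmentation of real recordings inevitably produces such
boundary clips, and without them the classifier treats every
activity-offset frame as out-of-distribution (typically misread as an
impact). Session rendering sums independently seeded entries over the bed
and peak-normalizes only if the mix clips, preserving transient crest
factors; one master seed splits into per-entry streams, so adding an entry
never perturbs the others.

Deliberately not modelled: room acoustics (reverberation, microphone
placement), source movement, and the amplitude statistics of any particular
home. Passing tests therefore demonstrate that the *pipeline* — features,
training procedure, quantization, voting — behaves as specified on
separable, realistically structured input; they do not certify accuracy on
field recordings, where inter-class confusion is far higher.

## Classifier

The model is intentionally tiny (≈ 20k parameters): stem 3×3 convolution to
8 channels + batch norm + ReLU; three residual stages of widths 8/16/32,
each one identity block (two 3×3 conv+BN with a skip; stride-2 and a 1×1
projection at stage entry); global average pooling; dense softmax head over
12 classes (the 11 sound labels plus background). It is implemented
directly in NumPy (im2col convolutions, explicit backward passes) — small
enough that a framework buys nothing, and the arithmetic is fully
inspectable; gradients are verified against central differences in float64.

Training: Adam at 1e-3, batch 64, up to 30 epochs with early stopping on
validation loss (patience 3, stratified 10% split), all seeded. On the
default synthetic task (500 train / 100 test clips per label) the task is
nearly separable and converges within a handful of epochs; the shared test
fixture caps at 8 epochs for that reason. Augmented rows should only ever
enter the training side; `dataset.split_pool` splits at the source-clip
level so oversampled repeats and masked copies never straddle the split.

Quantized inference emulates the deployed 8-bit path rather than binding to
a specific runtime: batch norms are folded into the preceding convolutions;
folded weights are per-tensor symmetric int8 (scale = max|w|/127);
activations pass through an affine int8 quantize/dequantize at each stage
boundary with min/max ranges calibrated on a representative feature sweep;
inputs are consumed through the int8 feature representation. The contract
is behavioural — ≥ 95% argmax agreement with the float path — not bit
equivalence with any particular interpreter.

## Post-processing

Frames arrive every 0.5 s (1 s windows, 50% overlap); decisions are made
once a 7-frame (3.5 s) buffer fills, then slide by one frame. Per label L
with threshold θ (default 0.5, per-label overridable):

* continuous L: occurred iff #{frames with p_L > θ} > 7/2 (strict; a tie is
  impossible with an odd buffer), confidence = mean of p_L over all 7
  frames;
* instant L: occurred iff any frame has p_L > θ, confidence = mean of the
  supra-threshold p_L only. A given frame can satisfy up to 7 overlapping
  buffers, so instant occurrences are deduplicated by frame index: credited
  to the first buffer containing the frame, suppressed afterwards.

Labels are judged independently — simultaneous sounds each get their own
event stream (dish clangs during dishwashing do not interrupt the water).

Activity assembly runs a per-label tolerance counter measured in buffers:
reset to the label's tolerance on every occurrence, decremented on every
miss, the activity closing when it goes below zero. Defaults: 10 buffers
(5 s) for continuous labels, 4 for instant ones. Times are stream seconds;
a frame's timestamp is its *center* (so instant activities align with the
true transient instant), and an activity spans the first to last occurred
buffer timestamp, making `duration = end − start` exact by construction.
The final filter drops records shorter than `min_duration` (default 0.5 s —
one hop, which also removes single-frame instant false alarms), below
`min_confidence` (default 0: confidence filtering is optional), or with
labels impossible at the node's location (editable exclusion table;
bathroom excludes tv/microwave/cooking by default).

Each energy-gated segment is post-processed independently: voting buffers
never straddle gated silence. This is safe because any gap long enough to
close the gate (> 5 s) also exhausts the continuous tolerance (5 s). A
side effect worth knowing: events inside a segment's first 3.5 s are
timestamped no earlier than the first full buffer, and segments shorter
than 3.5 s (7 frames) produce no decisions at all — transients should be
captured in context, not as isolated 1 s recordings.

## Scoring

Event-level scoring is artifact-defined (the deployed system was assessed
qualitatively): a truth interval counts as detected if a same-label
activity overlaps ≥ 50% of the truth duration; pairs are matched greedily
by overlap, one-to-one; precision/recall/F1 follow from matched counts. On
ten-minute scripted bathroom sessions the pipeline reaches event F1 ≥ 0.8
across seeds; residual misses are 0.5 s-grid alignment effects on ≤ 0.3 s
transients, not detection failures.

## Problem sizes and numerical choices

Defaults used by the tests and acceptance script: 12 classes; 500 train /
100 test clips per label for the end-to-end learning check; 300–2000 source
clips per label for the dataset-contract check; 1000 random windows for the
vote-oracle equality; 20 seeds for the flip-noise comparison; 3 seeds × 600 s
sessions end-to-end. Numerical details that matter: spectrogram arithmetic
in float64, features stored float32; dB floor via `max(M, 1e-10)`;
model weights float32 with He initialization; early-stopping improvements
below 1e-5 in validation loss are ignored; mask augmentation re-draws (up
to 8 times) if a mask lands entirely on already-floored cells, so an
augmented copy never equals its source.
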