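# Methods

## Signal model and preprocessing

Input recordings are mono 16-bit PCM WAV (other bit depths are rejected;
stereo is averaged to mono with a warning; sample rates are never resampled
automatically, so frame arithmetic stays exact). Pre-emphasis
`y[t] = x[t] − 0.95·x[t−1]` (first sample passes through, i.e. `x[−1] = 0`)
compensates high-frequency attenuation. Frames are 50 ms with 30% overlap:
at 44.1 kHz that is `frame_len = 2205` samples and
`hop = floor(0.7·2205) = 1543` — the non-integer hop is floored, giving
slightly more overlap, deterministically. A trailing partial frame is dropped
rather than zero-padded so it cannot dilute the energy maximum. Frames are
Hamming-windowed before anything else uses them.

Syllables are maximal runs of *vocal* frames, where a frame is vocal iff its
energy (computed on the windowed frame) is **strictly** greater than half the
maximum frame energy of that recording (ties count as silence; the maximum is
per recording, not per batch). Segments are reported with inclusive frame
indices and the half-open sample span those frames cover.

## Spectrogram front-ends

All three operate on the same windowed frame matrix, so their sample sets are
identical in size and label sequence by construction.

- **spe** — magnitude STFT; frames are zero-padded to `n_fft` = next power of
  two ≥ frame length (4096 at 44.1 kHz). Chosen for FFT efficiency; the paper
  trail of a window-length DFT is preserved by Parseval tests.
- **mel** — per frame: power spectrum → 64 triangular mel filters (HTK mel
  scale, 0 Hz–Nyquist) → log (floored at 1e−10 so silence never yields NaN)
  → orthonormal DCT-II → coefficients 0..31, of which the last 31 are kept.
  Dropping c0 removes the per-frame gain, making the representation invariant
  to positive rescaling. Filterbank size, mel scale variant and DCT
  normalisation are the common defaults and are isolated behind parameters.
- **ch** — chirplet decomposition. Atom:
  `atom(f, c)[n] = g[n]·exp(i2π(f·t + ½·c·t²))`, `t = n/rate`, `g` a Gaussian
  of width `σ = atom_len/6`, each atom normalised to unit energy, atom length
  equal to the frame length. The default bank has 48 centre frequencies
  geometrically spaced 500 Hz–16 kHz (capped at 0.45·rate) covering the
  passerine vocal range, and 9 chirp rates symmetric within ±250 Hz/ms
  including 0. The per-frame, per-centre coefficient is the maximum of
  |⟨frame, atom⟩| over rates. The exact dictionary of published fast-chirplet
  implementations varies; this bank is a stated, fully configurable choice
  serialized with outputs.

### Windows and images

Syllable segments are tiled with consecutive non-overlapping fixed-duration
windows (default 300 ms) starting at the segment start; a trailing short
window — or a syllable shorter than the duration — is centred on its content
and symmetrically zero-padded. Windows are cut from the pre-emphasised signal
and re-framed per window so every image has an identical frame grid across
durations. Rendering: magnitude → dB relative to the per-image maximum,
floored at −80 dB → per-image min–max normalisation (hence gain invariance)
→ a blue-to-red (jet) colormap, low frequencies at the bottom, time left to
right → bilinear resize to 224×224 RGB. An all-constant spectrogram maps to
the colormap minimum rather than dividing by zero.

## Identification model

The SFIM is a ResNet-style classifier built from scratch in numpy (the
package carries its own minimal CNN layer library — im2col convolutions,
batch normalisation, ReLU, global average pooling, linear layers, Adam — with
explicit backward passes). Ordering is ResNet-v1: conv → BN → ReLU inside a
block, ReLU after the residual addition; downsampling blocks (stride-2 conv
then stride-1 conv) use a 1×1 stride-2 projection (+BN) on the shortcut
because channel and spatial dimensions change. Convolutions carry biases; He
initialisation for weights, zeros for biases, seeded. The classifier head of
a standalone SFIM is a single FC layer + softmax; the model splits exactly
into feature extractor (through pooling, a 256·w vector) and classifier.

`width_multiplier` scales the 32/64/128/256 channel counts and `input_size`
the image resolution. Both exist so the full method can run at desk scale;
width 1 at 224 px reproduces the reference geometry
(224×224×32 → 112×112×64 → 56×56×128 → 28×28×256, 4,353,042 parameters at
N = 18).

## Loss

With per-class sample fraction β_i (training split only, fixed before
training, so test composition never leaks) and η_i = (1−β_i)/β_i, the batch
cost is implemented literally as `(1/N_B) Σ β_{i_j}·WCE_{i_j}` with
`WCE_i = −η_i y_i log ŷ_i − (1−y_i) log(1−ŷ_i)`. For the true class the
second term vanishes and the β multiplier partially cancels η, so the cost
equals `(1/N_B) Σ (1−β)·(−log ŷ_true)`; this cancellation is pinned by tests
rather than assumed, so any future re-reading of the formula is a deliberate
change. Probabilities are clamped to [1e−7, 1−1e−7]. The training loop uses
the analytic softmax/cross-entropy gradient `u·(p − onehot)/N_B`, `u = 1−β`.

## Training

Adam (lr 0.001, β = 0.9/0.999, ε = 1e−8), batch size 50 by default
(configurable), up to 100 epochs. The split is stratified 7:3 per class
(round(0.7·count) to train, both sides kept non-empty) — stratified rather
than fully random so rare classes appear on both sides. Shuffling is reseeded
per epoch from the master seed; the last short batch is used, not dropped,
because the cost normalises by actual batch size. Early stopping monitors
test-split MAP with patience 10 (the monitored quantity is a choice; cost is
the alternative) and restores the best-MAP parameters including batch-norm
running statistics.

## Fusion

Backbones are frozen (per-parameter trainable flags; the optimizer skips
frozen parameters) and evaluated in inference mode, so channel vectors are
precomputed once per dataset and fusion training is cheap. The simplex
constraint on ω is enforced by construction via ω = softmax(raw) with raw
initialised to 0 (ω = 1/3 each); it therefore holds exactly after every
optimizer step. Result mode fuses post-softmax probabilities (the classifier
part is FC + softmax, so its output is the softmax); the fused vector is then
itself a probability vector. The head is FC(d→d) + ReLU + FC(d→N) + softmax
with the hidden size a parameter. Square head layers are initialised to the
identity so the initial decision is the fused channels' own and training only
refines it; at desk scale the tiny result-fusion head (d = N) sees too few
optimizer steps at lr 0.001 to unlearn a random initial mapping, whereas the
backbones' "≤ 20 epochs" budget does not constrain the cheap fusion stage,
which trains with the standard 100-epoch/patience-10 budget. Identity
initialisation can be disabled. Fusion checkpoints embed the three backbone
architecture hashes and verify them on load. Triples are aligned by
(clip, segment, window) key so every fusion example is one audio window seen
through three front-ends.

## Metrics

`map_paper` is macro accuracy: AveP(q) = accuracy over the samples of class
q, MAP = mean over classes; a class without test samples is an error. This
matches how single-species-recording studies in this area use "MAP" and is
deliberately named apart from retrieval mAP. `cmap_rankbased` ranks all
evaluated segments per ground-truth class by that class's score (no
threshold), ties broken stably by segment id; classes absent from the ground
truth are excluded from the average; a ground-truth class with no score
column contributes AveP = 0.

## Synthetic data generator

Each species is a harmonic linear-chirp syllable template: harmonic h sweeps
h·f_start → h·f_end with amplitude decay^(h−1) (harmonics reaching Nyquist
are omitted and logged), 10 ms raised-cosine ramps, durations uniform in
100–250 ms (the typical passerine syllable range), inter-syllable gaps
300–500 ms (always longer than one analysis frame so the detector can
separate syllables). White Gaussian noise is added at a prescribed SNR
measured over the voiced spans. One RNG stream per recording is derived from
(master seed, recording index), so extending a dataset never perturbs earlier
recordings.

Default species templates use moderate sweeps in the 4–7 kHz band. Two
reasons: typical songbird syllables span a fraction of an octave, and the
0.95 pre-emphasis filter's gain varies ~5× across a multi-octave sweep, which
would push syllable-onset frames below the half-max threshold and bias
detected onsets late — a property of the method, not of the detector
implementation. Linear chirps are deliberately the class signature the
chirplet front-end is matched to, mirroring (qualitatively only) the
advantage of that channel on real song.

What the generator does *not* emulate: real species' spectro-temporal
statistics (no syllable-internal modulation, no note structure), colored or
non-stationary background noise, overlapping vocalisations, reverberation, or
recording-chain variation. Passing tests therefore demonstrate that the
pipeline is implemented correctly and can learn separable spectro-temporal
classes under controlled noise — not field-condition accuracy.

## Problem sizes used by the test suite and acceptance script

The learnability study uses 3 species with 100/60/20 syllables (imbalanced),
300 ms windows, width-0.25 models at 32 px input, batch 16, ≤ 20 epochs per
backbone; segmentation recovery uses 50 recordings at 20 dB SNR; the
determinism check runs the chained pipeline twice at a reduced size. These
sizes are the package's desk-scale defaults: large enough that the trained
channels separate the classes and the fusion weights move, small enough to
run on a single CPU in minutes. Full-scale geometry (width 1, 224 px) is
exercised for architecture and parameter-count checks without training.

## Known limitations

- No data augmentation, denoising or band-pass pre-filtering anywhere.
- The numpy training loop is single-process and unsuited to datasets beyond
  a few thousand images.
- The chirplet bank is a stated stand-in; published fast-chirplet
  dictionaries differ and the bank should be tuned per corpus.
- MAP here is macro accuracy; numbers are not comparable to retrieval-style
  mAP values from other systems.
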