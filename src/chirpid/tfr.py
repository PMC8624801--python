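"""Time-frequency representations and fixed-size spectrogram images.

Three front-ends are computed from the same windowed frame matrix:

``spe``
    STFT magnitude spectrogram (linear frequency axis).
``mel``
    Mel spectrogram derived from the mel-frequency cepstral transform: 32
    MFCCs are computed per frame and the last 31 (dropping the overall-gain
    coefficient c0) form the spectrogram columns.
``ch``
    Chirplet spectrogram: each frame is projected on a bank of
    Gaussian-windowed linear-chirp atoms; per centre frequency the magnitude
    is maximised over chirp rates, so frequency-modulated syllables light up
    a compact ridge.

Fixed-duration windows cut from a recording are rendered as 224 x 224 RGB
images (dB scale, per-image min-max normalisation, blue-to-red colormap) — the
input unit of the identification models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from matplotlib import colormaps
from PIL import Image

from .audio import AudioClip
from .signal_prep import FrameMatrix, SyllableSegment

KINDS = ("spe", "mel", "ch")

IMAGE_SIZE = 224


@dataclass
class Spectrogram:
    coeffs: np.ndarray          # (n_frames, n_bins)
    kind: str                   # spe | mel | ch
    frame_times: np.ndarray     # seconds, frame starts
    bin_axis: np.ndarray        # Hz (spe, ch) or mel-coefficient index (mel)

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_bins(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class SpectrogramImage:
    """A 224 x 224 RGB rendering of one fixed-duration window."""

    pixels: np.ndarray          # (224, 224, 3) uint8
    kind: str
    window_start_s: float
    window_dur_ms: float
    label: str | None = None
    clip_id: str | None = None
    segment_idx: int = 0
    window_idx: int = 0

    @property
    def key(self) -> tuple:
        """Alignment key: same audio window across the three kinds."""
        return (self.clip_id, self.segment_idx, self.window_idx)


def _frame_times(fm: FrameMatrix) -> np.ndarray:
    return np.arange(fm.n_frames) * fm.hop / fm.sample_rate


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def stft_spectrogram(fm: FrameMatrix, n_fft: int | None = None) -> Spectrogram:
    """Magnitude STFT of a windowed frame matrix.

    Frames are zero-padded to ``n_fft`` (default: next power of two >=
    frame length, 4096 for 50 ms at 44.1 kHz); output has n_fft/2 + 1 bins.
    """
    if not fm.windowed:
        raise RuntimeError("stft_spectrogram expects a windowed FrameMatrix")
    if n_fft is None:
        n_fft = _next_pow2(fm.frame_len)
    if n_fft < fm.frame_len:
        raise ValueError(f"n_fft={n_fft} < frame_len={fm.frame_len}")
    coeffs = np.abs(scipy.fft.rfft(fm.frames, n=n_fft, axis=1))
    freqs = scipy.fft.rfftfreq(n_fft, d=1.0 / fm.sample_rate)
    return Spectrogram(coeffs, "spe", _frame_times(fm), freqs)


# ---------------------------------------------------------------------------
# Mel / MFCT front-end


def hz_to_mel(f):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular mel filterbank spanning 0 Hz to Nyquist, (n_mels, n_fft//2+1)."""
    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(nyquist), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = scipy.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


_LOG_FLOOR = 1e-10  # keeps log of exact-silence frames finite


def mfcc(fm: FrameMatrix, n_mfcc: int = 32, n_mels: int = 64,
         n_fft: int | None = None) -> np.ndarray:
    """Mel-frequency cepstral coefficients per frame, (n_frames, n_mfcc).

    Power spectrum -> mel filterbank -> log -> orthonormal DCT-II.
    """
    if not fm.windowed:
        raise RuntimeError("mfcc expects a windowed FrameMatrix")
    if n_fft is None:
        n_fft = _next_pow2(fm.frame_len)
    spec = np.abs(scipy.fft.rfft(fm.frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_mels, n_fft, fm.sample_rate)
    mel_energy = spec @ fb.T
    log_mel = np.log(np.maximum(mel_energy, _LOG_FLOOR))
    cep = scipy.fft.dct(log_mel, type=2, norm="ortho", axis=1)
    return cep[:, :n_mfcc]


def mel_spectrogram(fm: FrameMatrix, n_mfcc: int = 32, n_mels: int = 64,
                    n_fft: int | None = None) -> Spectrogram:
    """Mel spectrogram composed from the last 31 of 32 MFCCs.

    Dropping coefficient 0 removes the per-frame overall gain, so the
    retained coefficients are invariant to positive rescaling of the frames.
    """
    cep = mfcc(fm, n_mfcc=n_mfcc, n_mels=n_mels, n_fft=n_fft)
    coeffs = cep[:, 1:]
    return Spectrogram(coeffs, "mel", _frame_times(fm),
                       np.arange(1, n_mfcc, dtype=float))


# ---------------------------------------------------------------------------
# Chirplet front-end


@dataclass
class ChirpletBank:
    """A bank of Gaussian-windowed linear-chirp atoms.

    atom(f, c)[n] = g[n] * exp(i 2 pi (f t + 0.5 c t^2)), t = n / rate,
    g a Gaussian of width ``sigma`` samples, each atom normalised to unit
    energy. ``chirp_rates`` (Hz/s) must be symmetric about 0 and include 0.
    """

    center_freqs: np.ndarray    # (P,) Hz, strictly increasing
    chirp_rates: np.ndarray     # (Q,) Hz/s, Q odd, symmetric about 0
    atom_len: int               # samples
    sigma: float                # Gaussian width, samples
    sample_rate: int
    _atoms: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.center_freqs = np.asarray(self.center_freqs, dtype=np.float64)
        self.chirp_rates = np.asarray(self.chirp_rates, dtype=np.float64)
        if self.center_freqs.size < 1:
            raise ValueError("need at least one centre frequency")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("centre frequencies must be strictly increasing")
        if np.any(self.center_freqs >= self.sample_rate / 2):
            raise ValueError("centre frequencies must be below Nyquist")
        if self.chirp_rates.size % 2 != 1:
            raise ValueError("need an odd number of chirp rates (including 0)")
        if not np.allclose(self.chirp_rates + self.chirp_rates[::-1], 0.0):
            raise ValueError("chirp rates must be symmetric about 0")

    @property
    def n_centers(self) -> int:
        return self.center_freqs.size

    @property
    def n_rates(self) -> int:
        return self.chirp_rates.size

    def atoms(self) -> np.ndarray:
        """Complex atom matrix (P, Q, atom_len), lazily built and cached."""
        if self._atoms is None:
            n = np.arange(self.atom_len)
            t = n / self.sample_rate  # instantaneous frequency f + c*t from atom start
            g = np.exp(-0.5 * ((n - (self.atom_len - 1) / 2.0) / self.sigma) ** 2)
            f = self.center_freqs[:, None, None]
            c = self.chirp_rates[None, :, None]
            phase = 2.0 * np.pi * (f * t + 0.5 * c * t ** 2)
            atoms = g * np.exp(1j * phase)
            atoms /= np.linalg.norm(atoms, axis=2, keepdims=True)
            self._atoms = atoms.astype(np.complex128)
        return self._atoms


def default_chirplet_bank(sample_rate: int, atom_len: int,
                          n_centers: int = 48, f_lo: float = 500.0,
                          f_hi: float = 16000.0,
                          n_rates: int = 9,
                          max_rate_hz_per_ms: float = 250.0) -> ChirpletBank:
    """Bank covering the passerine vocal range.

    48 centre frequencies geometrically spaced 500 Hz-16 kHz (capped below
    Nyquist), 9 chirp rates symmetric within +-250 Hz per ms, Gaussian width
    sigma = atom_len / 6.
    """
    f_hi = min(f_hi, 0.45 * sample_rate)
    centers = np.geomspace(f_lo, f_hi, n_centers)
    rates = np.linspace(-max_rate_hz_per_ms * 1000.0,
                        max_rate_hz_per_ms * 1000.0, n_rates)
    return ChirpletBank(centers, rates, atom_len, atom_len / 6.0, sample_rate)


def chirplet_spectrogram(fm: FrameMatrix, bank: ChirpletBank | None = None
                         ) -> Spectrogram:
    """Chirplet coefficients per frame: max over rates of |<frame, atom>|.

    Output has one bin per centre frequency; the rate reduction makes each
    bin respond to the best-matching frequency slope, which suits
    frequency-modulated syllables.
    """
    if not fm.windowed:
        raise RuntimeError("chirplet_spectrogram expects a windowed FrameMatrix")
    if bank is None:
        bank = default_chirplet_bank(fm.sample_rate, fm.frame_len)
    if bank.atom_len > fm.frame_len:
        raise ValueError(
            f"atom_len={bank.atom_len} > frame_len={fm.frame_len}")
    off = (fm.frame_len - bank.atom_len) // 2  # centre shorter atoms
    x = fm.frames[:, off:off + bank.atom_len]
    atoms = bank.atoms().reshape(bank.n_centers * bank.n_rates, bank.atom_len)
    inner = np.abs(x @ atoms.conj().T)          # (n_frames, P*Q)
    inner = inner.reshape(fm.n_frames, bank.n_centers, bank.n_rates)
    coeffs = inner.max(axis=2)
    return Spectrogram(coeffs, "ch", _frame_times(fm), bank.center_freqs.copy())


def chirplet_best_rates(fm: FrameMatrix, bank: ChirpletBank) -> np.ndarray:
    """Chirp rate (Hz/s) maximising |<frame, atom>| per frame and centre."""
    off = (fm.frame_len - bank.atom_len) // 2
    x = fm.frames[:, off:off + bank.atom_len]
    atoms = bank.atoms().reshape(bank.n_centers * bank.n_rates, bank.atom_len)
    inner = np.abs(x @ atoms.conj().T).reshape(
        fm.n_frames, bank.n_centers, bank.n_rates)
    return bank.chirp_rates[np.argmax(inner, axis=2)]


# ---------------------------------------------------------------------------
# Fixed-duration windows and image rendering


def slice_windows(clip: AudioClip, segments: list[SyllableSegment],
                  duration_ms: float) -> list[AudioClip]:
    """Cut consecutive non-overlapping fixed-duration windows from syllables.

    Windows start at the segment start. A trailing short window (or a syllable
    shorter than the duration) is centred on its content and symmetrically
    zero-padded to exactly the requested duration. Each returned clip records
    its (clip_id, start_s) provenance; window/segment indices are positional.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    win = int(round(duration_ms * clip.sample_rate / 1000.0))
    out: list[AudioClip] = []
    for seg in segments:
        s0 = seg.start_sample
        s1 = min(seg.end_sample, len(clip))
        span = s1 - s0
        n_full = span // win
        for k in range(n_full):
            a = s0 + k * win
            out.append(AudioClip(clip.samples[a:a + win], clip.sample_rate,
                                 label=clip.label, clip_id=clip.clip_id,
                                 start_s=a / clip.sample_rate))
        rem = span - n_full * win
        if rem > 0:
            a = s0 + n_full * win
            content = clip.samples[a:s1]
            pad_l = (win - rem) // 2
            padded = np.zeros(win)
            padded[pad_l:pad_l + rem] = content
            out.append(AudioClip(padded, clip.sample_rate, label=clip.label,
                                 clip_id=clip.clip_id,
                                 start_s=a / clip.sample_rate))
    return out


_DB_FLOOR = -80.0


def render_image(spec: Spectrogram, *, size: int = IMAGE_SIZE,
                 cmap: str = "jet", window_start_s: float = 0.0,
                 window_dur_ms: float = 0.0, label: str | None = None,
                 clip_id: str | None = None, segment_idx: int = 0,
                 window_idx: int = 0) -> SpectrogramImage:
    """Render a spectrogram as an RGB image.

    Magnitudes go to dB relative to the spectrogram maximum (floored at
    -80 dB), are min-max normalised per image — so the rendering is invariant
    to positive gain — and mapped through a blue-to-red colormap. Time runs
    left to right, low bins sit at the bottom. The result is resized to
    ``size`` x ``size`` with bilinear interpolation. An all-constant
    spectrogram renders as a single colour (the colormap minimum).
    """
    if spec.coeffs.size == 0:
        raise ValueError("empty spectrogram")
    mag = np.abs(spec.coeffs.astype(np.float64))
    ref = mag.max()
    if ref > 0:
        db = 20.0 * np.log10(np.maximum(mag / ref, 10.0 ** (_DB_FLOOR / 20.0)))
    else:
        db = np.full_like(mag, _DB_FLOOR)
    lo, hi = db.min(), db.max()
    norm = (db - lo) / (hi - lo) if hi > lo else np.zeros_like(db)
    # (n_frames, n_bins) -> rows = bins with low frequency at the bottom
    grid = norm.T[::-1]
    rgb = colormaps[cmap](grid)[..., :3]
    img = Image.fromarray(np.ascontiguousarray((rgb * 255.0).round()
                                               .astype(np.uint8)))
    img = img.resize((size, size), Image.BILINEAR)
    return SpectrogramImage(np.asarray(img, dtype=np.uint8), spec.kind,
                            window_start_s, window_dur_ms, label=label,
                            clip_id=clip_id, segment_idx=segment_idx,
                            window_idx=window_idx)


def compute_spectrogram(fm: FrameMatrix, kind: str, *,
                        n_fft: int | None = None,
                        bank: ChirpletBank | None = None) -> Spectrogram:
    """Dispatch to the requested front-end (spe | mel | ch)."""
    if kind == "spe":
        return stft_spectrogram(fm, n_fft=n_fft)
    if kind == "mel":
        return mel_spectrogram(fm, n_fft=n_fft)
    if kind == "ch":
        return chirplet_spectrogram(fm, bank=bank)
    raise ValueError(f"unknown spectrogram kind: {kind!r}")
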