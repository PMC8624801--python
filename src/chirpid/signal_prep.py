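"""Pre-emphasis, framing, Hamming windowing and energy-based syllable segmentation.

A recording is pre-emphasised, cut into overlapping frames, windowed, and
frames whose energy exceeds half of the recording's maximum frame energy are
taken as vocal (syllable) frames; maximal runs of vocal frames become syllable
segments. Defaults follow field practice for passerine song: 50 ms frames,
30% overlap, pre-emphasis 0.95, half-maximum energy threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioClip


@dataclass
class FrameMatrix:
    """Overlapping frames of one clip with framing provenance."""

    frames: np.ndarray  # (n_frames, frame_len)
    frame_len: int
    hop: int
    sample_rate: int
    windowed: bool = False

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SyllableSegment:
    """One syllable located by the energy detector.

    Frame indices are inclusive; sample indices give the half-open span
    [start_sample, end_sample) covered by those frames.
    """

    start_frame: int
    end_frame: int
    start_sample: int
    end_sample: int
    peak_energy: float


def pre_emphasize(clip: AudioClip, coef: float = 0.95) -> AudioClip:
    """First-order high-pass y[t] = x[t] - coef*x[t-1]; y[0] = x[0].

    Compensates the high-frequency attenuation of vocalisation recordings.
    """
    if not 0.0 <= coef < 1.0:
        raise ValueError("pre-emphasis coefficient must be in [0, 1)")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coef * x[:-1]
    return AudioClip(y, clip.sample_rate, label=clip.label,
                     clip_id=clip.clip_id, start_s=clip.start_s)


def frame_signal(clip: AudioClip, frame_ms: float = 50.0,
                 overlap_frac: float = 0.3) -> FrameMatrix:
    """Cut a clip into overlapping frames.

    frame_len = round(frame_ms * rate / 1000); hop = floor((1-overlap) * frame_len).
    Frame k covers samples [k*hop, k*hop + frame_len); a trailing partial frame
    is dropped rather than zero-padded so it cannot distort the energy maximum.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must be in [0, 1)")
    frame_len = int(round(frame_ms * clip.sample_rate / 1000.0))
    hop = int(np.floor((1.0 - overlap_frac) * frame_len))
    if hop < 1:
        raise ValueError("overlap too large: hop would be zero samples")
    L = len(clip)
    if L < frame_len:
        raise ValueError(
            f"clip of {L} samples shorter than one frame ({frame_len} samples)"
        )
    n_frames = (L - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameMatrix(clip.samples[idx], frame_len, hop, clip.sample_rate)


def hamming_window(m: int) -> np.ndarray:
    """Hamming window w[n] = 0.54 - 0.46 cos(2 pi n / (M-1))."""
    if m == 1:
        return np.ones(1)
    n = np.arange(m)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (m - 1))


def apply_hamming(fm: FrameMatrix) -> FrameMatrix:
    """Multiply every frame by the Hamming window. Refuses to window twice."""
    if fm.windowed:
        raise RuntimeError("FrameMatrix is already windowed")
    w = hamming_window(fm.frame_len)
    return FrameMatrix(fm.frames * w[None, :], fm.frame_len, fm.hop,
                       fm.sample_rate, windowed=True)


def frame_energies(fm: FrameMatrix) -> np.ndarray:
    """Per-frame energy E_k = sum_n frame_k[n]^2."""
    return np.einsum("ij,ij->i", fm.frames, fm.frames)


def segment_syllables(fm: FrameMatrix, threshold_ratio: float = 0.5
                      ) -> list[SyllableSegment]:
    """Locate syllables as maximal runs of high-energy frames.

    A frame is vocal iff its energy is strictly greater than
    ``threshold_ratio`` times the maximum frame energy of this recording;
    everything else is silence. Energies are computed on the windowed frames.
    """
    if not fm.windowed:
        raise RuntimeError("segment_syllables expects a windowed FrameMatrix")
    if fm.n_frames == 0:
        raise ValueError("empty FrameMatrix")
    e = frame_energies(fm)
    voiced = e > threshold_ratio * e.max()
    segments: list[SyllableSegment] = []
    k = 0
    n = voiced.size
    while k < n:
        if voiced[k]:
            start = k
            while k + 1 < n and voiced[k + 1]:
                k += 1
            end = k
            segments.append(SyllableSegment(
                start_frame=start,
                end_frame=end,
                start_sample=start * fm.hop,
                end_sample=end * fm.hop + fm.frame_len,
                peak_energy=float(e[start:end + 1].max()),
            ))
        k += 1
    return segments


def segments_to_table(segments: list[SyllableSegment], clip: AudioClip
                      ) -> pd.DataFrame:
    """Tabulate segments as clip_id, start_sample, end_sample, start_s, end_s."""
    rate = clip.sample_rate
    rows = [
        {
            "clip_id": clip.clip_id or "",
            "start_sample": s.start_sample,
            "end_sample": s.end_sample,
            "start_s": s.start_sample / rate,
            "end_s": s.end_sample / rate,
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows, columns=["clip_id", "start_sample", "end_sample", "start_s", "end_s"]
    )


def write_segment_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
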