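"""Audio containers and 16-bit PCM WAV I/O."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and an optional species label.

    ``samples`` are dimensionless amplitudes stored as float64; integer PCM
    input is scaled to [-1, 1] at load time.
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    clip_id: str | None = None
    start_s: float = 0.0  # provenance of a sliced window within its source

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip must be mono (1-D samples)")
        if self.samples.size == 0:
            raise ValueError("AudioClip must be non-empty")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


def load_wav(path: str | Path, label: str | None = None) -> AudioClip:
    """Read a 16-bit PCM WAV file.

    Other bit depths are rejected; stereo input is averaged to mono with a
    logged warning. No resampling is performed, so frame arithmetic downstream
    stays exact.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise ValueError(
            f"{path}: expected 16-bit PCM WAV, got dtype {data.dtype}"
        )
    if data.ndim == 2:
        logger.warning("%s: stereo input averaged to mono", path)
        data = data.mean(axis=1)
    samples = np.asarray(data, dtype=np.float64) / 32768.0
    return AudioClip(samples, int(rate), label=label, clip_id=path.stem)


def save_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV, clipping amplitudes to [-1, 1]."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(Path(path), clip.sample_rate, pcm)
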