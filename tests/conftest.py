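import numpy as np
import pytest

from chirpid.audio import AudioClip
from chirpid.signal_prep import apply_hamming, frame_signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_clip():
    """One second of a 2 kHz tone at 44.1 kHz."""
    rate = 44100
    t = np.arange(rate) / rate
    return AudioClip(np.sin(2 * np.pi * 2000.0 * t), rate, label="tone",
                     clip_id="tone")


@pytest.fixture
def noise_frames(rng):
    """A windowed FrameMatrix of white noise at 44.1 kHz (paper framing)."""
    clip = AudioClip(rng.normal(0.0, 1.0, 22050), 44100)
    return apply_hamming(frame_signal(clip))
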