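"""Render the three spectrogram kinds of one syllable window.

Cuts a 300 ms window from a syllable, computes the STFT (spe), MFCT-derived
mel (mel) and chirplet (ch) spectrograms, and writes the three 224x224 RGB
images that the identification models consume.
"""

from pathlib import Path

import numpy as np
from PIL import Image

from chirpid import SpeciesSpec, generate_recording
from chirpid.pipeline import segment_clip
from chirpid.signal_prep import apply_hamming, frame_signal
from chirpid.tfr import compute_spectrogram, render_image, slice_windows

species = SpeciesSpec("demo_bird", f_start=4200.0, f_end=6200.0)
recording, _ = generate_recording(species, 2, 44100, 20.0,
                                  np.random.default_rng(1), clip_id="demo")
emphasised, _, segments = segment_clip(recording)
window = slice_windows(emphasised, segments[:1], duration_ms=300.0)[0]
frames = apply_hamming(frame_signal(window))

out_dir = Path("scratch/examples")
out_dir.mkdir(parents=True, exist_ok=True)
for kind in ("spe", "mel", "ch"):
    spec = compute_spectrogram(frames, kind)
    image = render_image(spec, window_dur_ms=300.0, clip_id="demo")
    path = out_dir / f"demo_{kind}.png"
    Image.fromarray(image.pixels).save(path)
    print(f"{kind}: {spec.n_frames} frames x {spec.n_bins} bins "
          f"-> {image.pixels.shape} image at {path}")

print("\nIn each image time runs left to right and frequency bottom to top;"
      "\nred marks high energy. The chirplet image concentrates the rising"
      "\nsweep into the most compact ridge of the three.")
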