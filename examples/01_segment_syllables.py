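"""Locate syllables in a recording by frame energy.

Generates one synthetic recording (a train of chirp syllables in 20 dB-SNR
noise), runs the pre-emphasis -> framing -> Hamming -> half-max-energy
detector, and prints the recovered boundaries next to the ground truth.
"""

import numpy as np

from chirpid import SpeciesSpec, generate_recording
from chirpid.pipeline import segment_clip
from chirpid.signal_prep import segments_to_table

species = SpeciesSpec("demo_bird", f_start=4500.0, f_end=5500.0)
recording, truth = generate_recording(species, n_syllables=4, rate=44100,
                                      snr_db=20.0,
                                      rng=np.random.default_rng(0),
                                      clip_id="demo")

emphasised, frames, segments = segment_clip(recording)
table = segments_to_table(segments, recording)

print(f"recording: {recording.duration_s:.2f} s, "
      f"{frames.n_frames} frames of {frames.frame_len} samples "
      f"(hop {frames.hop})")
print(table.to_string(index=False))
print("\nground truth onsets/offsets (samples):")
print(truth[["onset_sample", "offset_sample"]].to_string(index=False))
print("\nEach detected segment should match a true syllable to within one "
      "hop (~35 ms); intervening silence is never reported.")
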