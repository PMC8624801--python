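"""Pre-emphasis, framing, windowing and syllable segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpid.audio import AudioClip
from chirpid.signal_prep import (FrameMatrix, apply_hamming, frame_energies,
                                 frame_signal, hamming_window, pre_emphasize,
                                 segment_syllables, segments_to_table)
from chirpid.synthetic import SpeciesSpec, generate_recording


def clip(x, rate=44100):
    return AudioClip(np.asarray(x, dtype=float), rate)


class TestPreEmphasis:
    def test_constant_signal(self):
        out = pre_emphasize(clip([1.0, 1.0, 1.0]), 0.95)
        assert np.allclose(out.samples, [1.0, 0.05, 0.05])

    def test_zero_coefficient_is_identity(self, rng):
        x = rng.normal(size=64)
        assert np.array_equal(pre_emphasize(clip(x), 0.0).samples, x)

    def test_matches_recurrence_oracle(self, rng):
        x = rng.normal(size=1000)
        out = pre_emphasize(clip(x), 0.95).samples
        expected = np.empty(1000)
        expected[0] = x[0]
        for t in range(1, 1000):
            expected[t] = x[t] - 0.95 * x[t - 1]
        assert np.allclose(out, expected, rtol=0, atol=1e-15)

    def test_empty_clip_rejected(self):
        with pytest.raises(ValueError):
            AudioClip(np.array([]), 44100)

    @given(st.floats(-3, 3), st.floats(-3, 3), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=50), r.normal(size=50)
        lhs = pre_emphasize(clip(a * x + b * y), 0.95).samples
        rhs = (a * pre_emphasize(clip(x), 0.95).samples
               + b * pre_emphasize(clip(y), 0.95).samples)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestFraming:
    def test_paper_settings_arithmetic(self):
        fm = frame_signal(clip(np.zeros(44100)), frame_ms=50, overlap_frac=0.3)
        assert fm.frame_len == 2205
        assert fm.hop == 1543  # floor(0.7 * 2205)

    def test_exact_frame_count(self):
        L = 2205 + 2 * 1543
        fm = frame_signal(clip(np.zeros(L)))
        assert fm.n_frames == 3

    def test_short_clip_rejected(self):
        with pytest.raises(ValueError):
            frame_signal(clip(np.zeros(2204)))

    def test_frame_k_covers_expected_samples(self, rng):
        x = rng.normal(size=10000)
        fm = frame_signal(clip(x, rate=8000), frame_ms=50, overlap_frac=0.3)
        for k in (0, 1, fm.n_frames - 1):
            assert np.array_equal(fm.frames[k],
                                  x[k * fm.hop:k * fm.hop + fm.frame_len])

    @given(st.integers(10, 5000), st.integers(10, 400),
           st.floats(0.0, 0.8))
    @settings(max_examples=60, deadline=None)
    def test_frame_count_formula(self, extra, frame_len, overlap):
        # rate chosen so frame_ms maps exactly onto frame_len samples
        rate = 1000 * frame_len
        L = frame_len + extra
        fm = frame_signal(clip(np.zeros(L), rate=rate), frame_ms=1.0,
                          overlap_frac=overlap)
        assert fm.frame_len == frame_len
        assert fm.n_frames == (L - fm.frame_len) // fm.hop + 1


class TestHamming:
    def test_endpoint_and_midpoint(self):
        w = hamming_window(2205)
        assert w[0] == pytest.approx(0.08)
        odd = hamming_window(101)
        assert odd[50] == pytest.approx(1.0)

    def test_windowed_energy_matches_loop_oracle(self):
        fm = FrameMatrix(np.ones((1, 2205)), 2205, 1543, 44100)
        out = apply_hamming(fm)
        expected = sum((0.54 - 0.46 * np.cos(2 * np.pi * n / 2204)) ** 2
                       for n in range(2205))
        assert frame_energies(out)[0] == pytest.approx(expected, rel=1e-12)

    def test_double_windowing_rejected(self, noise_frames):
        with pytest.raises(RuntimeError):
            apply_hamming(noise_frames)


def frames_with_energies(energies, frame_len=10):
    e = np.asarray(energies, dtype=float)
    frames = np.sqrt(e / frame_len)[:, None] * np.ones((e.size, frame_len))
    return FrameMatrix(frames, frame_len, frame_len, 1000, windowed=True)


class TestSegmentation:
    def test_two_runs_by_inspection(self):
        segs = segment_syllables(frames_with_energies([0, 10, 9, 0, 8, 0]))
        assert [(s.start_frame, s.end_frame) for s in segs] == [(1, 2), (4, 4)]

    def test_uniform_energy_single_segment(self):
        segs = segment_syllables(frames_with_energies([3.0] * 7))
        assert len(segs) == 1
        assert (segs[0].start_frame, segs[0].end_frame) == (0, 6)

    def test_requires_windowed_frames(self, rng):
        fm = FrameMatrix(rng.normal(size=(3, 10)), 10, 10, 1000)
        with pytest.raises(RuntimeError):
            segment_syllables(fm)

    @given(st.lists(st.one_of(st.just(0.0), st.floats(1e-3, 100.0)),
                    min_size=1, max_size=60),
           st.floats(0.1, 0.9))
    @settings(max_examples=60, deadline=None)
    def test_segments_reconstruct_voiced_frames(self, energies, thr):
        fm = frames_with_energies(energies)
        segs = segment_syllables(fm, thr)
        e = np.asarray(energies)
        voiced = set(np.flatnonzero(e > thr * e.max()))
        covered = set()
        prev_end = -1
        for s in segs:
            assert s.start_frame <= s.end_frame
            assert s.start_frame > prev_end  # disjoint and ordered
            prev_end = s.end_frame
            covered.update(range(s.start_frame, s.end_frame + 1))
        assert covered == voiced

    def test_recovers_bursts_within_one_hop(self):
        spec = SpeciesSpec("s", 4500.0, 5500.0)
        r = np.random.default_rng(7)
        rec, truth = generate_recording(spec, 2, 44100, 20.0, r)
        emph = pre_emphasize(rec, 0.95)
        fm = apply_hamming(frame_signal(emph))
        segs = segment_syllables(fm)
        assert len(segs) == 2
        for s, (a, b) in zip(segs, truth[["onset_sample",
                                          "offset_sample"]].to_numpy()):
            assert abs(s.start_sample - a) <= fm.hop
            assert abs(s.end_sample - b) <= fm.hop

    def test_sample_span_consistent_with_frames(self):
        segs = segment_syllables(frames_with_energies([0, 5, 5, 0]))
        s = segs[0]
        assert s.start_sample == s.start_frame * 10
        assert s.end_sample == s.end_frame * 10 + 10


def test_segment_table_columns(tone_clip):
    fm = apply_hamming(frame_signal(tone_clip))
    df = segments_to_table(segment_syllables(fm), tone_clip)
    assert list(df.columns) == ["clip_id", "start_sample", "end_sample",
                                "start_s", "end_s"]
    assert (df["end_s"] > df["start_s"]).all()
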