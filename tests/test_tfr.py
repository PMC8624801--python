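"""Spectrogram front-ends, window slicing and image rendering."""

import dataclasses

import numpy as np
import pytest

from chirpid.audio import AudioClip
from chirpid.signal_prep import FrameMatrix, SyllableSegment
from chirpid.tfr import (ChirpletBank, chirplet_best_rates,
                         chirplet_spectrogram, default_chirplet_bank,
                         mel_filterbank, mel_spectrogram, render_image,
                         slice_windows, stft_spectrogram)

RATE = 44100


def rect_frames(frames, rate=RATE):
    """FrameMatrix flagged windowed without actually windowing (test mode)."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    return FrameMatrix(frames, frames.shape[1], frames.shape[1], rate,
                       windowed=True)


class TestStft:
    def test_zero_frames_zero_spectrogram(self):
        spec = stft_spectrogram(rect_frames(np.zeros((3, 256))), n_fft=256)
        assert spec.kind == "spe"
        assert spec.coeffs.shape == (3, 129)
        assert np.all(spec.coeffs == 0)

    def test_pure_tone_peaks_at_its_bin(self):
        n = 512
        for b in (5, 37, 100):
            t = np.arange(n)
            frame = np.cos(2 * np.pi * b * t / n)
            spec = stft_spectrogram(rect_frames(np.tile(frame, (4, 1))),
                                    n_fft=n)
            assert np.all(spec.coeffs.argmax(axis=1) == b)

    def test_parseval_energy(self, rng):
        n = 1024
        x = rng.normal(size=(5, n))
        spec = stft_spectrogram(rect_frames(x), n_fft=n)
        c = spec.coeffs ** 2
        onesided = (c[:, 0] + 2 * c[:, 1:-1].sum(axis=1) + c[:, -1]) / n
        assert np.allclose(onesided, (x ** 2).sum(axis=1), rtol=1e-6)

    def test_small_nfft_rejected(self, noise_frames):
        with pytest.raises(ValueError):
            stft_spectrogram(noise_frames, n_fft=1024)

    def test_frame_count_preserved(self, noise_frames):
        assert stft_spectrogram(noise_frames).n_frames == noise_frames.n_frames


class TestMel:
    def test_output_width_is_31(self, noise_frames):
        spec = mel_spectrogram(noise_frames, n_mfcc=32)
        assert spec.kind == "mel"
        assert spec.n_bins == 31
        assert spec.n_frames == noise_frames.n_frames

    def test_gain_lives_in_dropped_c0(self, noise_frames):
        scaled = dataclasses.replace(noise_frames,
                                     frames=noise_frames.frames * 7.3)
        a = mel_spectrogram(noise_frames).coeffs
        b = mel_spectrogram(scaled).coeffs
        assert np.allclose(a, b, atol=1e-8)

    def test_silent_frames_finite(self):
        spec = mel_spectrogram(rect_frames(np.zeros((2, 2205))))
        assert np.all(np.isfinite(spec.coeffs))

    def test_matches_step_by_step_oracle(self, rng):
        """Straight-line reference: |FFT|^2 -> triangles -> log -> explicit DCT."""
        n_fft, n_mels, n_mfcc = 1024, 64, 32
        x = rng.normal(size=(4, n_fft))
        fm = rect_frames(x)
        got = mel_spectrogram(fm, n_mfcc=n_mfcc, n_mels=n_mels,
                              n_fft=n_fft).coeffs
        power = np.abs(np.fft.rfft(x, n_fft, axis=1)) ** 2
        fb = mel_filterbank(n_mels, n_fft, RATE)
        logm = np.log(np.maximum(power @ fb.T, 1e-10))
        # orthonormal DCT-II written out
        k = np.arange(n_mels)
        dct = np.cos(np.pi * np.outer(np.arange(n_mels), (2 * k + 1))
                     / (2 * n_mels))
        dct *= np.sqrt(2.0 / n_mels)
        dct[0] /= np.sqrt(2.0)
        expected = (logm @ dct.T)[:, 1:n_mfcc]
        assert np.allclose(got, expected, atol=1e-5)


class TestChirplet:
    def small_bank(self, atom_len=512):
        return default_chirplet_bank(RATE, atom_len, n_centers=16,
                                     n_rates=5)

    def test_zero_frames_zero_coefficients(self):
        bank = self.small_bank()
        spec = chirplet_spectrogram(rect_frames(np.zeros((2, 512))), bank)
        assert spec.kind == "ch"
        assert spec.coeffs.shape == (2, 16)
        assert np.all(spec.coeffs == 0)

    def test_matched_atom_self_detection(self):
        bank = self.small_bank()
        atoms = bank.atoms()
        for p, q in [(3, 0), (8, 4), (12, 2)]:
            frame = atoms[p, q].real
            fm = rect_frames(frame)
            spec = chirplet_spectrogram(fm, bank)
            # brute-force inner products over the whole bank
            brute = np.array([[abs(np.vdot(atoms[i, j], frame))
                               for j in range(bank.n_rates)]
                              for i in range(bank.n_centers)])
            assert spec.coeffs[0].argmax() == p == brute.max(axis=1).argmax()
            assert np.allclose(spec.coeffs[0], brute.max(axis=1))
            best = chirplet_best_rates(fm, bank)
            assert best[0, p] == bank.chirp_rates[q] == \
                bank.chirp_rates[brute[p].argmax()]

    def test_pure_tone_selects_zero_rate(self):
        bank = self.small_bank()
        p = 9
        t = np.arange(512) / RATE
        frame = np.sin(2 * np.pi * bank.center_freqs[p] * t)
        best = chirplet_best_rates(rect_frames(frame), bank)
        assert best[0, p] == 0.0

    def test_sign_flip_invariance(self, rng):
        bank = self.small_bank()
        x = rng.normal(size=(3, 512))
        a = chirplet_spectrogram(rect_frames(x), bank).coeffs
        b = chirplet_spectrogram(rect_frames(-x), bank).coeffs
        assert np.allclose(a, b)

    def test_atom_longer_than_frame_rejected(self):
        bank = self.small_bank(atom_len=1024)
        with pytest.raises(ValueError):
            chirplet_spectrogram(rect_frames(np.zeros((1, 512))), bank)

    def test_bank_validation(self):
        with pytest.raises(ValueError):
            ChirpletBank(np.array([500.0, 400.0]), np.array([0.0]), 64, 10.0,
                         RATE)
        with pytest.raises(ValueError):
            ChirpletBank(np.array([500.0]), np.array([-1.0, 1.0]), 64, 10.0,
                         RATE)
        with pytest.raises(ValueError):
            ChirpletBank(np.array([30000.0]), np.array([0.0]), 64, 10.0, RATE)


def seg(start, end, frame_len=2205, hop=1543):
    return SyllableSegment(0, 0, start, end, 1.0)


class TestSliceWindows:
    def test_window_sample_count(self):
        clip = AudioClip(np.ones(44100), RATE)
        wins = slice_windows(clip, [seg(0, 26460)], 300.0)
        assert all(len(w) == 13230 for w in wins)  # 0.3 * 44100

    def test_short_syllable_single_padded_window(self):
        clip = AudioClip(np.ones(44100), RATE)
        n250 = int(0.25 * RATE)
        wins = slice_windows(clip, [seg(1000, 1000 + n250)], 300.0)
        assert len(wins) == 1
        w = wins[0].samples
        assert len(w) == 13230
        pad = (13230 - n250) // 2
        assert np.all(w[:pad] == 0) and np.all(w[-pad:] == 0)
        assert np.all(w[pad:pad + n250] == 1)

    def test_650ms_segment_gives_three_windows(self):
        clip = AudioClip(np.ones(2 * RATE), RATE)
        n650 = int(0.65 * RATE)
        wins = slice_windows(clip, [seg(0, n650)], 300.0)
        assert len(wins) == 3
        assert all(len(w) == 13230 for w in wins)

    def test_empty_segment_list(self, tone_clip):
        assert slice_windows(tone_clip, [], 300.0) == []

    def test_nonpositive_duration_rejected(self, tone_clip):
        with pytest.raises(ValueError):
            slice_windows(tone_clip, [], 0.0)


class TestRenderImage:
    def test_shape_dtype_range(self, noise_frames):
        img = render_image(stft_spectrogram(noise_frames))
        assert img.pixels.shape == (224, 224, 3)
        assert img.pixels.dtype == np.uint8

    def test_constant_spectrogram_uniform_image(self):
        spec = stft_spectrogram(rect_frames(np.zeros((4, 256))), n_fft=256)
        img = render_image(spec)
        assert np.all(img.pixels == img.pixels[0, 0])

    def test_gain_invariance(self, noise_frames):
        a = render_image(stft_spectrogram(noise_frames)).pixels
        scaled = dataclasses.replace(noise_frames,
                                     frames=noise_frames.frames * 123.0)
        b = render_image(stft_spectrogram(scaled)).pixels
        assert np.array_equal(a, b)

    def test_high_energy_renders_red_low_blue(self):
        # one hot column: energy concentrated in a high bin
        coeffs = np.full((8, 64), 1e-9)
        coeffs[:, 50] = 1.0
        spec = stft_spectrogram(rect_frames(np.zeros((8, 126)), rate=1000),
                                n_fft=126)
        spec = dataclasses.replace(spec, coeffs=coeffs)
        px = render_image(spec).pixels.astype(int)
        # row index of max red should be above (smaller index than) mid-height
        red_rows = px[..., 0].sum(axis=1)
        blue_rows = px[..., 2].sum(axis=1)
        assert red_rows.argmax() < 112      # high frequency at the top
        assert blue_rows.argmax() != red_rows.argmax()
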