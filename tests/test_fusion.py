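"""Fusion weights, fusion topologies, frozen-backbone training."""

import numpy as np
import pytest

from chirpid.fusion import (FusionModel, FusionWeights, build_fusion_model,
                            fuse, self_omega, train_fusion, triple_arrays)
from chirpid.nn import Adam
from chirpid.sfim import ModelSpec, build_sfim, sfim_parameter_count
from chirpid.tfr import SpectrogramImage
from chirpid.training import SampleSet, TrainConfig, split_dataset


class TestFuse:
    def test_identical_vectors_unchanged(self, rng):
        v = rng.normal(size=32)
        w = FusionWeights()
        w.raw.data[...] = rng.normal(size=3).astype(np.float32)
        assert np.allclose(fuse([v, v, v], w), v, atol=1e-12)

    def test_vertex_selects_single_channel(self, rng):
        ys = [rng.normal(size=10) for _ in range(3)]
        assert np.array_equal(fuse(ys, np.array([1.0, 0.0, 0.0])), ys[0])

    def test_matches_loop_oracle(self, rng):
        ys = [rng.normal(size=50) for _ in range(3)]
        omega = rng.dirichlet([1, 1, 1])
        got = fuse(ys, omega)
        expected = np.zeros(50)
        for i in range(50):
            for n in range(3):
                expected[i] += omega[n] * ys[n][i]
        assert np.allclose(got, expected, atol=1e-9)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse([np.zeros(3), np.zeros(4), np.zeros(3)], FusionWeights())

    def test_permutation_equivariance(self, rng):
        ys = [rng.normal(size=20) for _ in range(3)]
        omega = rng.dirichlet([1, 1, 1])
        perm = [2, 0, 1]
        a = fuse(ys, omega)
        b = fuse([ys[i] for i in perm], omega[perm])
        assert np.allclose(a, b, atol=1e-12)


class TestSimplexInvariant:
    def test_simplex_after_random_optimizer_steps(self, rng):
        fw = FusionWeights()
        opt = Adam([fw.raw], lr=0.05)
        for _ in range(1000):
            opt.zero_grad()
            fw.raw.grad += rng.normal(size=3).astype(np.float32)
            opt.step()
            w = fw.omega
            assert abs(w.sum() - 1.0) < 1e-6
            assert np.all(w >= 0)

    def test_uniform_initialisation(self):
        assert np.allclose(FusionWeights().omega, 1.0 / 3.0)


def tiny_backbones(n_classes=3, seed=0):
    spec = ModelSpec(n_classes, width_multiplier=0.125, input_size=16)
    return [build_sfim(spec, seed=seed + i) for i in range(3)]


def colour_image(value, kind, label, clip_id, seg, win):
    px = np.full((16, 16, 3), value, dtype=np.uint8)
    return SpectrogramImage(px, kind, 0.0, 300.0, label=label,
                            clip_id=clip_id, segment_idx=seg, window_idx=win)


def triple_set(n_per_class=8, informative_channel=0, seed=0):
    """Class identity encoded in one channel's pixel level only."""
    rng = np.random.default_rng(seed)
    items = []
    for c in range(3):
        for j in range(n_per_class):
            imgs = []
            for ch, kind in enumerate(("spe", "mel", "ch")):
                if ch == informative_channel:
                    val = 40 + 80 * c + rng.integers(0, 10)
                else:
                    val = 128
                imgs.append(colour_image(int(val), kind, f"c{c}",
                                         f"clip{c}", j, 0))
            items.append((tuple(imgs), c))
    return SampleSet(items, 3, "triple", ["c0", "c1", "c2"])


class TestFusionModel:
    def test_trainable_count_ordering(self):
        """Re-fuse < Fe-fuse < full SFIM at N=18, width 1."""
        n, d = 18, 256
        refuse = 3 + (n * n + n) + (n * n + n)
        fefuse = 3 + (d * d + d) + (d * n + n)
        sfim_total = sfim_parameter_count(18, 1.0)
        assert refuse < fefuse < sfim_total
        bbs = tiny_backbones(18)
        dd = bbs[0].spec.feature_dim
        re_model = build_fusion_model(bbs, "result", 18)
        fe_model = build_fusion_model(bbs, "feature", 18)
        assert re_model.trainable_parameter_count == 3 + 2 * (18 * 18 + 18)
        assert fe_model.trainable_parameter_count == \
            3 + (dd * dd + dd) + (dd * 18 + 18)
        assert re_model.trainable_parameter_count < \
            fe_model.trainable_parameter_count < sum(
                p.size for p in bbs[0].params())

    def test_result_mode_prehead_is_probability_vector(self, rng):
        bbs = tiny_backbones()
        fm = build_fusion_model(bbs, "result", 3)
        x = [rng.random((4, 3, 16, 16)).astype(np.float32) for _ in range(3)]
        v = fm.channel_vectors(x)
        fused = fm.fused_vector(v)
        assert np.allclose(fused.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(fused >= 0)

    def test_vertex_weight_reproduces_backbone_softmax(self, rng):
        bbs = tiny_backbones()
        fm = build_fusion_model(bbs, "result", 3, identity_init=False)
        fm.fw.raw.data[...] = np.array([60.0, 0.0, 0.0], dtype=np.float32)
        x = [rng.random((5, 3, 16, 16)).astype(np.float32) for _ in range(3)]
        v = fm.channel_vectors(x)
        assert np.allclose(fm.fused_vector(v), bbs[0].forward(x[0]),
                           atol=1e-6)

    def test_backbone_mismatch_rejected(self):
        bbs = tiny_backbones()
        other = build_sfim(ModelSpec(4, 0.125, 16), seed=9)
        with pytest.raises(ValueError):
            build_fusion_model([bbs[0], bbs[1], other], "result", 3)

    def test_frozen_backbones_bit_identical_after_training_step(self):
        bbs = tiny_backbones()
        before = [{p.name: p.data.copy() for p in b.params()} for b in bbs]
        fm = build_fusion_model(bbs, "feature", 3)
        ss = triple_set()
        cfg = TrainConfig(batch_size=8, max_epochs=1, patience=1, seed=0)
        tr, te = split_dataset(ss, 0.7, 0)
        train_fusion(fm, tr, te, cfg)
        for b, snap in zip(bbs, before):
            for p in b.params():
                assert np.array_equal(p.data, snap[p.name])


class _InformativeStub:
    """Backbone stub that decodes the class planted in the pixel level."""

    def __init__(self, n_classes=3, input_size=16):
        self.spec = ModelSpec(n_classes, 0.125, input_size)

    def freeze(self):
        pass

    def forward(self, x, train=False):
        mean = x.mean(axis=(1, 2, 3)) * 255.0
        c = np.clip(np.round((mean - 40.0) / 80.0), 0, 2).astype(int)
        probs = np.full((x.shape[0], 3), 0.05, dtype=np.float32)
        probs[np.arange(x.shape[0]), c] = 0.9
        return probs

    def features(self, x, train=False):
        raise NotImplementedError


class _ConstantStub(_InformativeStub):
    """Backbone stub whose output ignores the input entirely."""

    def forward(self, x, train=False):
        return np.full((x.shape[0], 3), 1.0 / 3.0, dtype=np.float32)


class TestFusionTraining:
    def test_informative_channel_gains_weight(self):
        """Channels 2 and 3 are constant-output stubs; omega_1 should win."""
        bbs = [_InformativeStub(), _ConstantStub(), _ConstantStub()]
        fm = build_fusion_model(bbs, "result", 3, seed=4)
        ss = triple_set(n_per_class=10, informative_channel=0, seed=4)
        tr, te = split_dataset(ss, 0.7, 4)
        cfg = TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=60,
                          patience=60, seed=4)
        train_fusion(fm, tr, te, cfg)
        w = fm.fw.omega
        assert w[0] > max(w[1], w[2])

    def test_cost_decreases_and_history_records_omega(self):
        bbs = tiny_backbones(seed=1)
        fm = build_fusion_model(bbs, "result", 3, seed=1)
        ss = triple_set(seed=1)
        tr, te = split_dataset(ss, 0.7, 1)
        cfg = TrainConfig(batch_size=8, max_epochs=8, patience=8, seed=1)
        hist = train_fusion(fm, tr, te, cfg)
        assert hist[-1]["cost"] <= hist[0]["cost"]
        assert all(abs(sum(h["omega"]) - 1.0) < 1e-6 for h in hist)

    def test_seeded_training_is_reproducible(self):
        results = []
        for _ in range(2):
            bbs = tiny_backbones(seed=2)
            fm = build_fusion_model(bbs, "result", 3, seed=2)
            ss = triple_set(seed=2)
            tr, te = split_dataset(ss, 0.7, 2)
            cfg = TrainConfig(batch_size=8, max_epochs=3, patience=3, seed=2)
            train_fusion(fm, tr, te, cfg)
            results.append(np.concatenate(
                [p.data.ravel() for p in fm.trainable_params()]))
        assert np.array_equal(results[0], results[1])

    def test_checkpoint_roundtrip_verifies_backbone_hashes(self, tmp_path):
        bbs = tiny_backbones(seed=6)
        fm = build_fusion_model(bbs, "result", 3, seed=6)
        fm.save(tmp_path / "fuse")
        loaded = FusionModel.load(tmp_path / "fuse", bbs)
        assert np.allclose(loaded.fw.omega, fm.fw.omega)
        wrong = tiny_backbones(n_classes=3, seed=7)
        wrong[0] = build_sfim(ModelSpec(3, 0.25, 16), seed=7)
        with pytest.raises(ValueError):
            FusionModel.load(tmp_path / "fuse", wrong)
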