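"""Adaptive linear weighted fusion of three frozen single-feature models.

Three SFIMs — one per spectrogram kind (spe, mel, ch) — are frozen and their
outputs combined by a learned convex combination F = sum_n omega_n y_n with
sum omega_n = 1. The simplex constraint is enforced by construction through
the re-parameterisation omega = softmax(raw), so it holds exactly after every
optimizer step. Two topologies:

feature fusion (Fe-fuse)
    fuses the three pooled feature vectors (length 256*w) before the head;
result fusion (Re-fuse)
    fuses the three softmax probability vectors (length N), so the fused
    vector is itself a probability vector and the head is much smaller.

The head is two fully-connected layers and a softmax: FC(d -> hidden) + ReLU
+ FC(hidden -> N), hidden defaulting to d. Only the fusion weights and the
head train; backbone features are therefore precomputed once per dataset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .losses import ClassWeights, class_weights, cost_logit_grad
from .metrics import map_paper
from .nn import Adam, Linear, Param, ReLU, softmax
from .training import EarlyStopper, SampleSet, TrainConfig, images_to_array

MODES = ("feature", "result")


class FusionWeights:
    """Simplex-constrained channel weights omega = softmax(raw)."""

    def __init__(self, n_channels: int = 3):
        self.raw = Param(np.zeros(n_channels, dtype=np.float32), "fusion.raw")

    @property
    def omega(self) -> np.ndarray:
        return softmax(self.raw.data.astype(np.float64))

    def accumulate_grad(self, domega: np.ndarray) -> None:
        """Chain a gradient w.r.t. omega through the softmax Jacobian."""
        w = self.omega
        self.raw.grad += (w * (domega - np.dot(domega, w))).astype(np.float32)


def fuse(vectors, fw: FusionWeights | np.ndarray) -> np.ndarray:
    """Weighted sum F = sum_n omega_n y_n of equally shaped vectors."""
    omega = fw.omega if isinstance(fw, FusionWeights) else np.asarray(fw)
    if len(vectors) != omega.size:
        raise ValueError("number of vectors does not match number of weights")
    shapes = {np.shape(v) for v in vectors}
    if len(shapes) != 1:
        raise ValueError("vectors to fuse must have identical shape")
    out = np.zeros_like(np.asarray(vectors[0], dtype=np.float64))
    for w, v in zip(omega, vectors):
        out += w * np.asarray(v, dtype=np.float64)
    return out


class FusionModel:
    """Three frozen backbones, learned fusion weights and a two-layer head."""

    def __init__(self, backbones, mode: str, n_classes: int,
                 hidden: int | None = None,
                 rng: np.random.Generator | None = None,
                 identity_init: bool = True):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if len(backbones) != 3:
            raise ValueError("exactly three backbones expected")
        dims = {b.spec.n_classes for b in backbones}
        if dims != {n_classes}:
            raise ValueError("backbone class counts disagree")
        widths = {b.spec.feature_dim for b in backbones}
        if len(widths) != 1:
            raise ValueError("backbone widths disagree")
        rng = rng or np.random.default_rng(0)
        self.mode = mode
        self.n_classes = n_classes
        self.backbones = list(backbones)
        for b in self.backbones:
            b.freeze()
        self.fused_dim = (backbones[0].spec.feature_dim
                          if mode == "feature" else n_classes)
        self.hidden = hidden or self.fused_dim
        self.fw = FusionWeights(3)
        self.fc1 = Linear(self.fused_dim, self.hidden, rng, "head.fc1")
        self.relu = ReLU()
        self.fc2 = Linear(self.hidden, n_classes, rng, "head.fc2")
        if identity_init:
            # Square head layers start as the identity, so the model's initial
            # decision is the fused channels' own (pass-through head) and
            # training only refines it — important at desk scale where the
            # tiny result-fusion head sees few optimizer steps.
            if self.hidden == self.fused_dim:
                self.fc1.weight.data[...] = np.eye(self.hidden,
                                                   self.fused_dim,
                                                   dtype=np.float32)
            if n_classes == self.hidden:
                self.fc2.weight.data[...] = np.eye(n_classes, self.hidden,
                                                   dtype=np.float32)
        self._cache_v = None

    # -- channels ------------------------------------------------------------

    def channel_vectors(self, x_triple) -> np.ndarray:
        """Frozen-backbone outputs for a (x_spe, x_mel, x_ch) batch triple.

        Feature mode uses the pooled feature vectors, result mode the softmax
        outputs. Returns (B, 3, d).
        """
        outs = []
        for backbone, x in zip(self.backbones, x_triple):
            if self.mode == "feature":
                outs.append(backbone.features(x, train=False))
            else:
                outs.append(backbone.forward(x, train=False))
        return np.stack(outs, axis=1).astype(np.float32)

    # -- trainable part ------------------------------------------------------

    def head_logits(self, v: np.ndarray, train: bool = False) -> np.ndarray:
        """v: (B, 3, d) channel vectors -> logits. Caches for backward."""
        omega = self.fw.omega.astype(np.float32)
        z = np.einsum("n,bnd->bd", omega, v)
        self._cache_v = v
        h = self.relu.forward(self.fc1.forward(z, train), train)
        return self.fc2.forward(h, train)

    def fused_vector(self, v: np.ndarray) -> np.ndarray:
        """The pre-head fused vector F for a (B, 3, d) channel batch."""
        return np.einsum("n,bnd->bd", self.fw.omega, v.astype(np.float64))

    def forward_from_channels(self, v: np.ndarray, train: bool = False
                              ) -> np.ndarray:
        return softmax(self.head_logits(v, train))

    def forward(self, x_triple, train: bool = False) -> np.ndarray:
        return self.forward_from_channels(self.channel_vectors(x_triple), train)

    __call__ = forward

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(dlogits)))
        v = self._cache_v
        domega = np.einsum("bd,bnd->n", dz.astype(np.float64),
                           v.astype(np.float64))
        self.fw.accumulate_grad(domega)

    def trainable_params(self) -> list[Param]:
        return [self.fw.raw] + self.fc1.params() + self.fc2.params()

    @property
    def trainable_parameter_count(self) -> int:
        return sum(p.size for p in self.trainable_params())

    def get_state(self) -> dict:
        return {p.name: p.data.copy() for p in self.trainable_params()}

    def set_state(self, state: dict) -> None:
        for p in self.trainable_params():
            p.data[...] = state[p.name]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{p.name: p.data for p in self.trainable_params()})
        meta = {
            "mode": self.mode,
            "n_classes": self.n_classes,
            "hidden": self.hidden,
            "omega": self.fw.omega.tolist(),
            "backbone_hashes": [b.architecture_hash for b in self.backbones],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path, backbones) -> "FusionModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        hashes = [b.architecture_hash for b in backbones]
        if hashes != meta["backbone_hashes"]:
            raise ValueError("backbone architecture hashes do not match checkpoint")
        model = cls(backbones, meta["mode"], meta["n_classes"], meta["hidden"])
        data = np.load(path.with_suffix(".npz"))
        model.set_state({p.name: data[p.name] for p in model.trainable_params()})
        return model


def build_fusion_model(backbones, mode: str, n_classes: int,
                       hidden: int | None = None,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None,
                       identity_init: bool = True) -> FusionModel:
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    return FusionModel(backbones, mode, n_classes, hidden, rng,
                       identity_init=identity_init)


def triple_arrays(ss: SampleSet, input_size: int) -> tuple[list, np.ndarray]:
    """Split a triple SampleSet into per-kind image arrays + labels."""
    if ss.kind != "triple":
        raise ValueError("fusion training needs a triple sample set")
    xs = []
    for n in range(3):
        xs.append(images_to_array([item[n] for item, _ in ss.items],
                                  input_size))
    return xs, ss.labels


def train_fusion(fm: FusionModel, train: SampleSet, test: SampleSet,
                 cfg: TrainConfig, weights: ClassWeights | None = None
                 ) -> list[dict]:
    """Train fusion weights + head on precomputed frozen-backbone outputs.

    Optimises the weighted cross-entropy cost; the simplex constraint on
    omega holds by construction every step. History records per-epoch cost,
    test MAP and omega.
    """
    size = fm.backbones[0].spec.input_size
    x_train, y_train = triple_arrays(train, size)
    x_test, y_test = triple_arrays(test, size)
    v_train = fm.channel_vectors(x_train)
    v_test = fm.channel_vectors(x_test)
    if weights is None:
        weights = class_weights(train.class_counts)
    opt = Adam(fm.trainable_params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    stopper = EarlyStopper(cfg.patience)
    history: list[dict] = []
    n = v_train.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        costs = []
        for start in range(0, n, cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            vb, yb = v_train[sel], y_train[sel]
            probs = fm.forward_from_channels(vb, train=True)
            p_true = np.clip(probs[np.arange(len(sel)), yb], 1e-7, 1.0)
            u = (weights.beta * weights.eta)[yb]
            costs.append(float(np.mean(u * -np.log(p_true))))
            opt.zero_grad()
            fm.backward(cost_logit_grad(probs, yb, weights))
            opt.step()
        pred = np.argmax(fm.forward_from_channels(v_test), axis=1)
        test_map = map_paper(pred, y_test, train.n_classes)
        history.append({"epoch": epoch, "cost": float(np.mean(costs)),
                        "map": test_map, "omega": self_omega(fm)})
        if stopper.update(epoch, test_map, fm.get_state()):
            break
    if stopper.best_state is not None:
        fm.set_state(stopper.best_state)
    return history


def self_omega(fm: FusionModel) -> list[float]:
    return [float(w) for w in fm.fw.omega]
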