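"""Single feature identification model (SFIM): a compact residual CNN.

Architecture (at width multiplier 1, input 224 x 224 x 3):

    stem conv 3x3, 32, stride 1
    2 identity residual blocks @ 32          -> 224 x 224 x 32
    downsampling block 32 -> 64 (stride 2)
    2 identity blocks @ 64                   -> 112 x 112 x 64
    downsampling block 64 -> 128
    2 identity blocks @ 128                  -> 56 x 56 x 128
    downsampling block 128 -> 256
    2 identity blocks @ 256                  -> 28 x 28 x 256
    global average pool -> fully connected -> softmax over N species

Every conv is followed by batch normalisation; ReLU sits before the residual
addition inside a block and after it (ResNet-v1 ordering). Downsampling blocks
use a 1x1 stride-2 projection (+BN) on the shortcut; identity blocks add the
input unchanged. The model splits into a feature extractor (through the
pooling, emitting a 256*w vector) and a classifier (FC + softmax), which is
what the fusion models freeze and reuse.

``width_multiplier`` scales all channel counts for desk-scale experiments;
``input_size`` scales the image resolution (spatial sizes scale with it).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Layer, Linear,
                 Param, ReLU, softmax)

BASE_CHANNELS = (32, 64, 128, 256)


@dataclass
class ModelSpec:
    n_classes: int
    width_multiplier: float = 1.0
    input_size: int = 224

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(max(1, round(c * self.width_multiplier))
                     for c in BASE_CHANNELS)

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]


class _ConvBN(Layer):
    def __init__(self, c_in, c_out, ksize, stride, rng, name):
        self.conv = Conv2d(c_in, c_out, ksize, stride, rng, name)
        self.bn = BatchNorm2d(c_out, name=f"{name}.bn")

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=False):
        return self.bn.forward(self.conv.forward(x, train), train)

    def backward(self, dout):
        return self.conv.backward(self.bn.backward(dout))


class IdentityBlock(Layer):
    """Two 3x3 convs with an identity shortcut; output = relu(F(x) + x)."""

    def __init__(self, channels: int, rng: np.random.Generator, name: str):
        self.cb1 = _ConvBN(channels, channels, 3, 1, rng, f"{name}.1")
        self.relu1 = ReLU()
        self.cb2 = _ConvBN(channels, channels, 3, 1, rng, f"{name}.2")
        self.relu_out = ReLU()

    def params(self):
        return self.cb1.params() + self.cb2.params()

    def forward(self, x, train=False):
        h = self.relu1.forward(self.cb1.forward(x, train), train)
        f = self.cb2.forward(h, train)
        return self.relu_out.forward(f + x, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dx_branch = self.cb1.backward(self.relu1.backward(self.cb2.backward(d)))
        return dx_branch + d


class DownsampleBlock(Layer):
    """Stride-2 conv then stride-1 conv, with a 1x1 stride-2 projection shortcut."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str):
        self.cb1 = _ConvBN(c_in, c_out, 3, 2, rng, f"{name}.1")
        self.relu1 = ReLU()
        self.cb2 = _ConvBN(c_out, c_out, 3, 1, rng, f"{name}.2")
        self.proj = _ConvBN(c_in, c_out, 1, 2, rng, f"{name}.proj")
        self.relu_out = ReLU()

    def params(self):
        return self.cb1.params() + self.cb2.params() + self.proj.params()

    def forward(self, x, train=False):
        h = self.relu1.forward(self.cb1.forward(x, train), train)
        f = self.cb2.forward(h, train)
        s = self.proj.forward(x, train)
        return self.relu_out.forward(f + s, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dx = self.cb1.backward(self.relu1.backward(self.cb2.backward(d)))
        dx += self.proj.backward(d)
        return dx


class SfimModel:
    """The residual classifier, exposing its extractor/classifier split.

    ``forward`` returns class probabilities; ``features`` stops at the pooled
    feature vector. ``backward`` propagates a gradient with respect to the
    logits through the whole network, accumulating parameter gradients.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        ch = spec.channels
        self.stem = _ConvBN(3, ch[0], 3, 1, rng, "stem")
        self.stem_relu = ReLU()
        stages: list[Layer] = []
        self._stage_ends: list[int] = []
        for i, c in enumerate(ch):
            if i > 0:
                stages.append(DownsampleBlock(ch[i - 1], c, rng, f"down{i}"))
            stages.append(IdentityBlock(c, rng, f"stage{i}.block1"))
            stages.append(IdentityBlock(c, rng, f"stage{i}.block2"))
            self._stage_ends.append(len(stages) - 1)
        self.stages = stages
        self.gap = GlobalAvgPool()
        self.fc = Linear(spec.feature_dim, spec.n_classes, rng, "classifier.fc")

    # -- forward / backward -------------------------------------------------

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.stem_relu.forward(self.stem.forward(x, train), train)
        for layer in self.stages:
            h = layer.forward(h, train)
        return self.gap.forward(h, train)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.fc.forward(self.features(x, train), train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return softmax(self.logits(x, train))

    __call__ = forward

    def stage_outputs(self, x: np.ndarray) -> list[np.ndarray]:
        """Activations at the end of each channel stage (for shape audits)."""
        h = self.stem_relu.forward(self.stem.forward(x, False), False)
        outs = []
        for i, layer in enumerate(self.stages):
            h = layer.forward(h, False)
            if i in self._stage_ends:
                outs.append(h)
        return outs

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.gap.backward(self.fc.backward(dlogits))
        for layer in reversed(self.stages):
            d = layer.backward(d)
        self.stem.backward(self.stem_relu.backward(d))

    # -- parameters ----------------------------------------------------------

    def params(self) -> list[Param]:
        out = self.stem.params()
        for layer in self.stages:
            out += layer.params()
        return out + self.fc.params()

    def feature_params(self) -> list[Param]:
        out = self.stem.params()
        for layer in self.stages:
            out += layer.params()
        return out

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    @property
    def trainable_parameter_count(self) -> int:
        return sum(p.size for p in self.params() if p.trainable)

    def freeze(self) -> None:
        for p in self.params():
            p.trainable = False

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data[...] = values[p.name]

    def get_params(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params()}

    def _bn_layers(self) -> list[BatchNorm2d]:
        bns = [self.stem.bn]
        for layer in self.stages:
            for attr in ("cb1", "cb2", "proj"):
                cb = getattr(layer, attr, None)
                if cb is not None:
                    bns.append(cb.bn)
        return bns

    # -- persistence ---------------------------------------------------------

    @property
    def architecture_hash(self) -> str:
        desc = json.dumps({
            "n_classes": self.spec.n_classes,
            "width_multiplier": self.spec.width_multiplier,
            "input_size": self.spec.input_size,
            "channels": self.spec.channels,
        }, sort_keys=True)
        return hashlib.sha256(desc.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        """Write weights as .npz plus a JSON sidecar with spec + hash."""
        path = Path(path)
        arrays = {p.name: p.data for p in self.params()}
        for i, bn in enumerate(self._bn_layers()):
            arrays[f"__running_mean_{i}"] = bn.running_mean
            arrays[f"__running_var_{i}"] = bn.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "n_classes": self.spec.n_classes,
            "width_multiplier": self.spec.width_multiplier,
            "input_size": self.spec.input_size,
            "architecture_hash": self.architecture_hash,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SfimModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = ModelSpec(meta["n_classes"], meta["width_multiplier"],
                         meta["input_size"])
        model = cls(spec)
        if model.architecture_hash != meta["architecture_hash"]:
            raise ValueError("checkpoint architecture hash mismatch")
        data = np.load(path.with_suffix(".npz"))
        model.set_params({p.name: data[p.name] for p in model.params()})
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean[...] = data[f"__running_mean_{i}"]
            bn.running_var[...] = data[f"__running_var_{i}"]
        return model


def build_sfim(spec: ModelSpec, rng: np.random.Generator | None = None,
               seed: int | None = None) -> SfimModel:
    """Construct an SFIM with He-normal conv init and zero biases."""
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    return SfimModel(spec, rng)


class FeatureExtractor:
    """The model through global average pooling: image -> 256*w vector."""

    def __init__(self, model: SfimModel):
        self._model = model

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self._model.features(x, train)

    @property
    def output_dim(self) -> int:
        return self._model.spec.feature_dim

    def params(self) -> list[Param]:
        return self._model.feature_params()


class Classifier:
    """The classification part: FC layer + softmax."""

    def __init__(self, model: SfimModel):
        self._model = model

    def __call__(self, feat: np.ndarray) -> np.ndarray:
        return softmax(self._model.fc.forward(feat))

    def params(self) -> list[Param]:
        return self._model.fc.params()


def split_model(model: SfimModel) -> tuple[FeatureExtractor, Classifier]:
    """Partition an SFIM into its feature-extraction and classifier parts.

    Both views share the model's parameters, so composing them reproduces the
    full model exactly.
    """
    return FeatureExtractor(model), Classifier(model)


def sfim_parameter_count(n_classes: int, width_multiplier: float = 1.0) -> int:
    """Closed-form parameter tally, independent of model construction.

    Per conv: k*k*c_in*c_out + c_out (bias); per batch norm: 2*c; the FC
    layer: d*N + N. Downsampling blocks add a 1x1 projection conv + BN.
    """
    ch = [max(1, round(c * width_multiplier)) for c in BASE_CHANNELS]

    def conv(cin, cout, k=3):
        return k * k * cin * cout + cout

    def bn(c):
        return 2 * c

    total = conv(3, ch[0]) + bn(ch[0])                      # stem
    for i, c in enumerate(ch):
        if i > 0:
            total += conv(ch[i - 1], c) + bn(c)             # stride-2 conv
            total += conv(c, c) + bn(c)                     # stride-1 conv
            total += conv(ch[i - 1], c, k=1) + bn(c)        # projection
        for _ in range(2):                                  # identity blocks
            total += 2 * (conv(c, c) + bn(c))
    total += ch[-1] * n_classes + n_classes                 # FC
    return total
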