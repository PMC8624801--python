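"""Dataset splitting, the SFIM training loop and early stopping.

Training follows a fixed recipe: Adam, learning rate 0.001, batch size 50
(configurable for desk-scale runs), up to 100 epochs, minimising the
imbalance-weighted cross-entropy cost with class weights computed from the
training split only. The test-set macro accuracy (MAP) is monitored each
epoch; training halts when it has not improved for ``patience`` epochs and
the best-MAP parameters are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .losses import ClassWeights, class_weights, cost_logit_grad
from .metrics import map_paper
from .nn import Adam
from .sfim import SfimModel
from .tfr import SpectrogramImage


@dataclass
class TrainConfig:
    batch_size: int = 50
    learning_rate: float = 0.001
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0 or self.patience < 1:
            raise ValueError("invalid training configuration")


@dataclass
class SampleSet:
    """Labelled images (or aligned image triples) ready for training.

    ``kind`` is one of spe/mel/ch for single-channel sets or ``triple`` for
    key-aligned (spe, mel, ch) tuples feeding the fusion models.
    """

    items: list  # (SpectrogramImage | tuple of 3 SpectrogramImage, class_idx)
    n_classes: int
    kind: str
    class_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, y in self.items], dtype=np.int64)

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


def split_dataset(ss: SampleSet, train_frac: float = 0.7, seed: int = 0
                  ) -> tuple[SampleSet, SampleSet]:
    """Stratified random split: per class, round(train_frac * count) to train.

    Stratification keeps rare classes present on both sides. Reproducible
    given the seed; a class with fewer than 2 items cannot be split.
    """
    labels = ss.labels
    counts = ss.class_counts
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 items to split")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in range(ss.n_classes):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides non-empty
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    mk = lambda sel: SampleSet([ss.items[i] for i in sel], ss.n_classes,
                               ss.kind, ss.class_names)
    return mk(train_idx), mk(test_idx)


def image_to_array(img: SpectrogramImage, input_size: int) -> np.ndarray:
    """uint8 HWC pixels -> float32 CHW in [0, 1], resized if needed."""
    px = img.pixels
    if px.shape[0] != input_size:
        pil = Image.fromarray(px).resize((input_size, input_size),
                                         Image.BILINEAR)
        px = np.asarray(pil)
    return (px.astype(np.float32) / 255.0).transpose(2, 0, 1)


def images_to_array(images, input_size: int) -> np.ndarray:
    return np.stack([image_to_array(im, input_size) for im in images])


def sampleset_arrays(ss: SampleSet, input_size: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    x = images_to_array([im for im, _ in ss.items], input_size)
    return x, ss.labels


class EarlyStopper:
    """Patience-based early stopping on a to-be-maximised metric.

    Strict improvement resets the counter; after ``patience`` epochs without
    improvement ``update`` returns True and ``best_state`` holds the snapshot
    taken at the best epoch.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.best_state = None
        self._since = 0

    def update(self, epoch: int, metric: float, state) -> bool:
        if metric > self.best:
            self.best = metric
            self.best_epoch = epoch
            self.best_state = state
            self._since = 0
        else:
            self._since += 1
        return self._since >= self.patience


def predict_proba(model: SfimModel, x: np.ndarray, batch_size: int = 64
                  ) -> np.ndarray:
    out = [model.forward(x[i:i + batch_size], train=False)
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out, axis=0)


def predict(model: SfimModel, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    return np.argmax(predict_proba(model, x, batch_size), axis=1)


def _model_state(model: SfimModel) -> dict:
    state = model.get_params()
    for i, bn in enumerate(model._bn_layers()):
        state[f"__rm_{i}"] = bn.running_mean.copy()
        state[f"__rv_{i}"] = bn.running_var.copy()
    return state


def _restore_state(model: SfimModel, state: dict) -> None:
    model.set_params({p.name: state[p.name] for p in model.params()})
    for i, bn in enumerate(model._bn_layers()):
        bn.running_mean[...] = state[f"__rm_{i}"]
        bn.running_var[...] = state[f"__rv_{i}"]


def train_sfim(model: SfimModel, train: SampleSet, test: SampleSet,
               cfg: TrainConfig, weights: ClassWeights | None = None
               ) -> list[dict]:
    """Train an SFIM, returning a per-epoch history of cost and test MAP.

    Class weights default to the training-split composition. Shuffling is
    reseeded each epoch from the master seed; the last short batch is kept
    (the cost normalises by the actual batch size). On return the model holds
    the best-test-MAP parameters.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    size = model.spec.input_size
    x_train, y_train = sampleset_arrays(train, size)
    x_test, y_test = sampleset_arrays(test, size)
    if weights is None:
        weights = class_weights(train.class_counts)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    stopper = EarlyStopper(cfg.patience)
    history: list[dict] = []
    n = x_train.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        costs = []
        for start in range(0, n, cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            probs = model.forward(xb, train=True)
            p_true = np.clip(probs[np.arange(len(sel)), yb], 1e-7, 1.0)
            u = (weights.beta * weights.eta)[yb]
            costs.append(float(np.mean(u * -np.log(p_true))))
            opt.zero_grad()
            model.backward(cost_logit_grad(probs, yb, weights))
            opt.step()
        test_map = map_paper(predict(model, x_test), y_test, train.n_classes)
        history.append({"epoch": epoch, "cost": float(np.mean(costs)),
                        "map": test_map})
        if stopper.update(epoch, test_map, _model_state(model)):
            break
    if stopper.best_state is not None:
        _restore_state(model, stopper.best_state)
    return history
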