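"""Imbalance-weighted cross-entropy.

Class weights are derived from training-set composition: with beta_i the
fraction of samples in class i, the class weight is eta_i = (1 - beta_i) /
beta_i, so rare classes weigh more. The per-sample loss for a sample of true
class i is

    WCE_i = -eta_i * y_i * log(p_i) - (1 - y_i) * log(1 - p_i)

which for the true class (y_i = 1) reduces to -eta_i * log(p_i). The batch
cost re-multiplies by beta_i and averages:

    Cost = (1 / N_B) * sum_j beta_{i_j} * WCE_{i_j}

Since beta * eta = 1 - beta, the cost equals the closed form
(1 / N_B) * sum_j (1 - beta_{i_j}) * (-log p_{j,true}); that identity is
pinned by tests so any re-reading of the formula is a deliberate change.
Probabilities are clamped to [eps, 1 - eps] (eps = 1e-7) to keep logs finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EPS = 1e-7


@dataclass
class ClassWeights:
    beta: np.ndarray  # per-class sample fraction, sums to 1
    eta: np.ndarray   # per-class weight (1 - beta) / beta

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.eta = np.asarray(self.eta, dtype=np.float64)
        if not np.isclose(self.beta.sum(), 1.0, atol=1e-9):
            raise ValueError("class fractions must sum to 1")
        if np.any(self.eta <= 0):
            raise ValueError("class weights must be positive")

    @property
    def n_classes(self) -> int:
        return self.beta.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": np.arange(self.n_classes),
                             "beta": self.beta, "eta": self.eta})

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ClassWeights":
        df = pd.read_csv(path, sep="\t")
        return cls(df["beta"].to_numpy(), df["eta"].to_numpy())


@dataclass
class BatchPrediction:
    """One-hot labels and predicted probabilities for a batch."""

    y_true: np.ndarray       # (N_B, N) one-hot
    y_pred: np.ndarray       # (N_B, N) probabilities

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=np.float64)
        self.y_pred = np.asarray(self.y_pred, dtype=np.float64)
        if self.y_true.shape != self.y_pred.shape:
            raise ValueError("label / prediction shape mismatch")
        if self.y_true.shape[0] < 1:
            raise ValueError("empty batch")
        if np.any(self.y_pred < 0) or np.any(self.y_pred > 1):
            raise ValueError("predicted probabilities outside [0, 1]")
        if not np.allclose(self.y_true.sum(axis=1), 1.0):
            raise ValueError("labels must be one-hot")

    @property
    def class_index(self) -> np.ndarray:
        return np.argmax(self.y_true, axis=1)


def class_weights(class_counts) -> ClassWeights:
    """Weights from per-class sample counts: beta_i = n_i / n, eta_i = (1-beta_i)/beta_i."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("every class needs at least one sample")
    beta = counts / counts.sum()
    return ClassWeights(beta, (1.0 - beta) / beta)


def wce_per_sample(bp: BatchPrediction, w: ClassWeights) -> np.ndarray:
    """Per-sample weighted cross-entropy (the true-class term)."""
    idx = bp.class_index
    p = np.clip(bp.y_pred[np.arange(len(idx)), idx], EPS, 1.0 - EPS)
    return -w.eta[idx] * np.log(p)


def batch_cost(bp: BatchPrediction, w: ClassWeights) -> float:
    """Mean over the batch of beta_i * WCE_i."""
    idx = bp.class_index
    return float(np.mean(w.beta[idx] * wce_per_sample(bp, w)))


def batch_cost_grad(bp: BatchPrediction, w: ClassWeights) -> np.ndarray:
    """Gradient of the batch cost with respect to the predicted probabilities.

    Only true-class entries contribute (the cost depends on p_true alone);
    entries where clamping is active get zero gradient.
    """
    idx = bp.class_index
    n_b = len(idx)
    p = bp.y_pred[np.arange(n_b), idx]
    grad = np.zeros_like(bp.y_pred)
    inside = (p > EPS) & (p < 1.0 - EPS)
    rows = np.arange(n_b)[inside]
    grad[rows, idx[inside]] = (
        -w.beta[idx[inside]] * w.eta[idx[inside]] / p[inside] / n_b)
    return grad


def cost_logit_grad(probs: np.ndarray, class_index: np.ndarray,
                    w: ClassWeights) -> np.ndarray:
    """Gradient of the batch cost with respect to pre-softmax logits.

    With per-sample weight u = beta * eta = 1 - beta on -log p_true, the
    softmax/cross-entropy shortcut gives dCost/dz = u * (p - onehot) / N_B.
    Used by the training loops.
    """
    n_b = probs.shape[0]
    u = (w.beta * w.eta)[class_index][:, None]
    d = probs.copy()
    d[np.arange(n_b), class_index] -= 1.0
    return (u * d / n_b).astype(np.float32)
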