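"""Evaluation metrics: macro per-class accuracy ("MAP") and rank-based cmAP.

``map_paper`` follows the bioacoustics-classification convention where the
average precision of class q is the identification accuracy over the samples
of class q, and MAP is the mean over classes — i.e. macro (balanced)
accuracy. This deliberately differs from retrieval-style mean average
precision; the rank-based quantity used by BirdCLEF-style evaluations is
exposed separately as ``cmap_rankbased``:

    AveP(c) = sum_k P(k) * rel(k) / n_rel(c),   cmAP = mean_c AveP(c)

with P(k) precision at cut-off k in the list of segments ranked by the class-c
score, rel(k) the relevance indicator, and the mean taken over classes present
in the ground truth. Both names are kept explicit to prevent silent confusion
between the two conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EvalResult:
    per_class_avep: np.ndarray
    map: float
    n_classes: int


def mean_average_precision(pred_classes, true_classes, n_classes: int
                           ) -> EvalResult:
    """Macro per-class accuracy; every class must have at least one sample."""
    pred = np.asarray(pred_classes, dtype=np.int64)
    true = np.asarray(true_classes, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("prediction / label length mismatch")
    avep = np.empty(n_classes)
    for q in range(n_classes):
        mask = true == q
        if not mask.any():
            raise ValueError(f"class {q} has no test samples; AveP undefined")
        avep[q] = np.mean(pred[mask] == q)
    return EvalResult(avep, float(avep.mean()), n_classes)


def map_paper(pred_classes, true_classes, n_classes: int) -> float:
    return mean_average_precision(pred_classes, true_classes, n_classes).map


def average_precision_ranked(rel: np.ndarray, n_rel: int | None = None) -> float:
    """AveP over one ranked list from its relevance indicator sequence."""
    rel = np.asarray(rel, dtype=np.float64)
    if n_rel is None:
        n_rel = int(rel.sum())
    if n_rel == 0:
        return 0.0
    k = np.arange(1, rel.size + 1)
    precision_at_k = np.cumsum(rel) / k
    return float(np.sum(precision_at_k * rel) / n_rel)


def cmap_rankbased(scores: np.ndarray, true_classes, segment_ids=None) -> float:
    """Class-wise mean of rank-based average precision.

    ``scores`` is (n_segments, n_classes); for each ground-truth class the
    segments are ranked by that class's score (descending, ties broken by
    stable segment-id order) and AveP is computed from which ranked segments
    truly belong to the class. Classes absent from the ground truth are
    excluded from the average.
    """
    scores = np.asarray(scores, dtype=np.float64)
    true = np.asarray(true_classes, dtype=np.int64)
    if scores.shape[0] != true.size:
        raise ValueError("scores / labels length mismatch")
    if segment_ids is None:
        segment_ids = np.arange(true.size)
    order_ids = np.argsort(segment_ids, kind="stable")
    present = np.unique(true)
    aveps = []
    for c in present:
        if c >= scores.shape[1]:
            aveps.append(0.0)  # no ranking for this ground-truth class
            continue
        # stable sort by descending score with segment-id tie-break
        ranked = order_ids[np.argsort(-scores[order_ids, c], kind="stable")]
        rel = (true[ranked] == c).astype(np.float64)
        aveps.append(average_precision_ranked(rel, int(rel.sum())))
    return float(np.mean(aveps))


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Prediction table: segment_id, true_label, predicted_label, score_<c>..."""
    return pd.read_csv(path, sep="\t")


def evaluate_prediction_table(df: pd.DataFrame) -> dict:
    """Compute MAP (and cmAP when per-class scores are present) from a table."""
    classes = sorted(set(df["true_label"]))
    to_idx = {c: i for i, c in enumerate(classes)}
    true = df["true_label"].map(to_idx).to_numpy()
    pred = df["predicted_label"].map(
        lambda c: to_idx.get(c, -1)).to_numpy()
    res = mean_average_precision(pred, true, len(classes))
    out = {
        "map": res.map,
        "per_class_avep": {str(c): float(a)
                           for c, a in zip(classes, res.per_class_avep)},
    }
    score_cols = [f"score_{c}" for c in classes]
    if all(col in df.columns for col in score_cols):
        scores = df[score_cols].to_numpy()
        out["cmap"] = cmap_rankbased(scores, true,
                                     df["segment_id"].to_numpy())
    return out


def write_metrics(metrics: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True))
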