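"""Weighted softmax-level late fusion and classification metrics.

The three cue branches (joints, bones, face) each output a per-class
probability vector; the fused score is the weighted sum

    F = W_joints * p_joints + W_bones * p_bones + W_face * p_face

and the prediction is the argmax (ties broken toward the lowest class
index).  Class labels are 0-based throughout (0..5 for the six behaviour
states).
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "fuse", "topk_accuracy", "confusion_counts", "per_class_topk_counts",
    "grid_search_weights", "evaluation_report",
]

N_CLASSES = 6


def _check_probs(p, name: str, n_classes: int) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape[-1] != n_classes:
        raise ValueError(f"{name}: expected {n_classes} class probabilities, "
                         f"got shape {p.shape}")
    if (p < 0).any():
        raise ValueError(f"{name}: negative probabilities")
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError(f"{name}: probabilities must sum to 1 (got {sums})")
    return p


def fuse(p_joints, p_bones, p_face, weights=(1.0, 1.0, 1.0),
         n_classes: int = N_CLASSES):
    """Weighted sum of branch probabilities -> (scores, predicted labels).

    Accepts single vectors or stacked (N, n_classes) arrays.  Weights must
    be nonnegative and not all zero.  Prediction is argmax with
    lowest-index tie-break (NumPy's argmax convention).
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,):
        raise ValueError("weights must be three scalars (joints, bones, face)")
    if (w < 0).any():
        raise ValueError("fusion weights must be nonnegative")
    if not w.any():
        raise ValueError("fusion weights must not all be zero")
    parts = [_check_probs(p, name, n_classes)
             for p, name in ((p_joints, "joints"), (p_bones, "bones"), (p_face, "face"))]
    shapes = {p.shape for p in parts}
    if len(shapes) != 1:
        raise ValueError(f"branch probability shapes differ: {shapes}")
    scores = w[0] * parts[0] + w[1] * parts[1] + w[2] * parts[2]
    labels = np.argmax(scores, axis=-1)
    return scores, labels


def topk_accuracy(scores, labels, k: int = 1) -> float:
    """Percentage of samples whose true label ranks in the top k scores."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.intp))
    if scores.shape[0] == 0:
        raise ValueError("topk_accuracy: empty input")
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels length mismatch")
    n_classes = scores.shape[1]
    if not 1 <= k <= n_classes:
        raise ValueError(f"k must lie in 1..{n_classes}")
    # stable descending rank; ties keep the lower class index first,
    # consistent with the argmax tie-break
    order = np.argsort(-scores, axis=1, kind="stable")
    hits = (order[:, :k] == labels[:, None]).any(axis=1)
    return float(hits.mean() * 100.0)


def confusion_counts(predictions, labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix M[true, predicted]; entries sum to the sample count."""
    predictions = np.asarray(predictions, dtype=np.intp)
    labels = np.asarray(labels, dtype=np.intp)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels length mismatch")
    for name, arr in (("predictions", predictions), ("labels", labels)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name}: class index out of range 0..{n_classes - 1}")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (labels, predictions), 1)
    return m


def per_class_topk_counts(scores, labels, k: int, n_classes: int = N_CLASSES) -> np.ndarray:
    """Per-true-class counts of samples whose label is in the top k scores."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    order = np.argsort(-scores, axis=1, kind="stable")
    hits = (order[:, :k] == labels[:, None]).any(axis=1)
    counts = np.zeros(n_classes, dtype=np.int64)
    np.add.at(counts, labels[hits], 1)
    return counts


def grid_search_weights(p_joints, p_bones, p_face, labels,
                        grid=None, n_classes: int = N_CLASSES):
    """Exhaustive search of fusion weights maximizing top-1 accuracy.

    The default grid is {0.1, ..., 1.0} per branch.  Returns
    ``(best_weights, best_top1)``; ties prefer the earliest grid point.
    """
    if grid is None:
        grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
    best_w, best_acc = None, -1.0
    for w in itertools.product(grid, repeat=3):
        scores, _ = fuse(p_joints, p_bones, p_face, w, n_classes)
        acc = topk_accuracy(scores, labels, 1)
        if acc > best_acc:
            best_w, best_acc = tuple(float(v) for v in w), acc
    return best_w, best_acc


def evaluation_report(scores, labels, n_classes: int = N_CLASSES) -> dict:
    """Standard metrics bundle: top-1/top-2, per-class counts, confusion."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    predictions = np.argmax(scores, axis=-1)
    support = np.bincount(labels, minlength=n_classes)
    return {
        "n_samples": int(labels.shape[0]),
        "top1_accuracy": topk_accuracy(scores, labels, 1),
        "top2_accuracy": topk_accuracy(scores, labels, 2),
        "per_class_support": support.tolist(),
        "per_class_top1_counts": per_class_topk_counts(scores, labels, 1, n_classes).tolist(),
        "per_class_top2_counts": per_class_topk_counts(scores, labels, 2, n_classes).tolist(),
        "confusion_matrix": confusion_counts(predictions, labels, n_classes).tolist(),
    }
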