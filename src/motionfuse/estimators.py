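"""Scikit-learn-style estimators for the three cue branches and their fusion.

``SkeletonActionClassifier`` (joints or bones stream, graph-convolutional
backbone), ``FaceActionClassifier`` (landmark-image encoding + the
MobileViTv2-style backbone) and ``LateFusionClassifier`` (weighted
softmax-level fusion) all follow the fit/predict/predict_proba protocol,
expose ``get_params``/``set_params`` and compose with scikit-learn model
selection.

Training uses SGD with Nesterov momentum (0.9), learning rate 0.01,
weight decay 1e-4, batch size 8 and cross-entropy loss by default — the
reference recipe; epochs and widths are typically reduced for desk-scale
runs.  All randomness (init, shuffling) flows from the ``seed`` parameter,
so fits are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .agcn import SkeletonBackbone
from .autodiff import Tensor
from .face import FaceScaler, face_to_image, fit_scaler, prepare_backbone_input
from .fusion import fuse, evaluation_report, grid_search_weights
from .graph import build_graph, partition_adjacency
from .io import FaceSequence
from .mobilevit import MobileViTv2

__all__ = ["SkeletonActionClassifier", "FaceActionClassifier",
           "LateFusionClassifier", "evaluate_branches"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _train_loop(model, X, y, *, epochs, batch_size, lr, momentum, nesterov,
                weight_decay, rng, eval_data=None, verbose=0,
                optimizer="sgd", lr_milestones=(0.6, 0.85), lr_decay=0.1):
    """Minibatch training with step decay; returns a per-epoch history list.

    The learning rate drops by ``lr_decay`` at the given epoch fractions
    (the usual step schedule for this model family).
    """
    if optimizer == "sgd":
        opt = nn.SGD(model.parameters(), lr=lr, momentum=momentum,
                     nesterov=nesterov, weight_decay=weight_decay)
    elif optimizer == "adam":
        opt = nn.Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    n = len(X)
    drop_epochs = {int(np.ceil(m * epochs)) for m in (lr_milestones or ())}
    history = []
    for epoch in range(epochs):
        if epoch in drop_epochs:
            opt.lr *= lr_decay
        model.train()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            logits = model(Tensor(X[idx]))
            loss = nn.cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
        if eval_data is not None:
            Xv, yv = eval_data
            probs = _batched_forward(model, Xv)
            row["val_top1"] = float((probs.argmax(axis=1) == yv).mean() * 100)
        history.append(row)
        if verbose:
            print("  ".join(f"{k}={v:.4g}" for k, v in row.items()))
    return history


def _batched_forward(model, X, batch_size: int = 32) -> np.ndarray:
    model.eval()
    outs = []
    for start in range(0, len(X), batch_size):
        outs.append(model(Tensor(X[start:start + batch_size])).data)
    return _softmax(np.concatenate(outs, axis=0))


class SkeletonActionClassifier(ClassifierMixin, BaseEstimator):
    """Graph-convolutional behaviour classifier on body-keypoint sequences.

    Parameters
    ----------
    branch : {"joints", "bones"}
        ``"joints"`` trains on raw coordinates; ``"bones"`` on per-frame
        child-minus-parent vectors (translation-invariant relational cue).
    graph_variant : {"our", "new"}
        skeleton layout; ``"our"`` adds the nose-shoulder and hip-mouth
        edges.
    base_channels : int
        first-stage width; 64 is the reference model, smaller values give
        proportionally cheaper desk-scale models.
    use_msst, use_mae, mae_stage, mae_in_place
        ablation switches for the multi-scale taps and frame attention.
    normalize : bool
        optionally center each sample on its frame-0 neck position and
        scale coordinates by the image diagonal.  Off by default: the
        backbone's input batch-norm layer standardizes each
        joint-coordinate channel already, and the explicit variant
        injects the frame-0 neck detection noise into every frame, which
        measurably hurts the subtle-motion classes.
    """

    def __init__(self, branch="joints", graph_variant="our", base_channels=64,
                 use_msst=True, use_mae=True, mae_stage=1, mae_in_place=None,
                 epochs=100, batch_size=8, learning_rate=0.01, momentum=0.9,
                 nesterov=True, weight_decay=1e-4, optimizer="sgd", n_classes=6,
                 normalize=False, image_size=(1280, 720), seed=0, verbose=0):
        self.branch = branch
        self.graph_variant = graph_variant
        self.base_channels = base_channels
        self.use_msst = use_msst
        self.use_mae = use_mae
        self.mae_stage = mae_stage
        self.mae_in_place = mae_in_place
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self.optimizer = optimizer
        self.n_classes = n_classes
        self.normalize = normalize
        self.image_size = image_size
        self.seed = seed
        self.verbose = verbose

    # -- preprocessing ---------------------------------------------------
    def _to_bones(self, X: np.ndarray) -> np.ndarray:
        graph = self.graph_
        bones = np.zeros_like(X)
        for child, parent in graph.parents.items():
            bones[:, :2, :, child] = X[:, :2, :, child] - X[:, :2, :, parent]
            bones[:, 2, :, child] = np.minimum(X[:, 2, :, child], X[:, 2, :, parent])
        root = graph.center_index
        bones[:, 2, :, root] = X[:, 2, :, root]
        return bones

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != 3 or X.shape[3] != self.graph_.num_joints:
            raise ValueError(f"expected X of shape (N, 3, T, "
                             f"{self.graph_.num_joints}), got {X.shape}")
        if self.branch == "bones":
            X = self._to_bones(X)
        elif self.branch != "joints":
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.normalize:
            X = X.copy()
            diag = float(np.hypot(*self.image_size))
            if self.branch == "joints":
                neck = X[:, :2, 0:1, self.graph_.center_index][..., None]
                X[:, :2] -= neck
            X[:, :2] /= diag
        return X

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y, eval_set=None):
        y = np.asarray(y, dtype=np.int64)
        self.graph_ = build_graph(self.graph_variant)
        self.classes_ = np.arange(self.n_classes)
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError(f"labels must lie in 0..{self.n_classes - 1}")
        Xp = self._prepare(X)
        rng = np.random.default_rng(self.seed)
        self.model_ = SkeletonBackbone(
            partition_adjacency(self.graph_), num_classes=self.n_classes,
            base_channels=self.base_channels, use_msst=self.use_msst,
            use_mae=self.use_mae, mae_stage=self.mae_stage,
            mae_in_place=self.mae_in_place, seed=self.seed)
        eval_data = None
        if eval_set is not None:
            Xv, yv = eval_set
            eval_data = (self._prepare(Xv), np.asarray(yv, dtype=np.int64))
        self.history_ = _train_loop(
            self.model_, Xp, y, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.learning_rate, momentum=self.momentum, nesterov=self.nesterov,
            weight_decay=self.weight_decay, optimizer=self.optimizer, rng=rng,
            eval_data=eval_data, verbose=self.verbose)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return _batched_forward(self.model_, self._prepare(X))

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


class FaceActionClassifier(ClassifierMixin, BaseEstimator):
    """Behaviour classifier on facial-landmark sequences.

    Each (60, 68, 3) sequence is encoded as a 68x60 pseudo-color image
    (coordinates and confidence scaled to 8 bits against the training
    split's coordinate maxima), resized, and classified by the
    MobileViTv2-style backbone.  ``width=1.5`` with ``input_size=256``
    is the reference configuration; desk-scale fits use a narrower width
    and smaller input.
    """

    def __init__(self, width=0.5, input_size=64, epochs=30, batch_size=8,
                 learning_rate=0.01, momentum=0.9, nesterov=True,
                 weight_decay=1e-4, optimizer="sgd", n_classes=6,
                 scaler_scope="train", seed=0, verbose=0):
        self.width = width
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self.optimizer = optimizer
        self.n_classes = n_classes
        self.scaler_scope = scaler_scope
        self.seed = seed
        self.verbose = verbose

    def _encode(self, X: np.ndarray, scaler: FaceScaler) -> np.ndarray:
        imgs = [prepare_backbone_input(face_to_image(FaceSequence(seq), scaler),
                                       self.input_size)
                for seq in X]
        return np.stack(imgs).astype(np.float32)

    def fit(self, X, y, eval_set=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.arange(self.n_classes)
        self.scaler_ = fit_scaler([FaceSequence(seq) for seq in X])
        Xp = self._encode(X, self.scaler_)
        rng = np.random.default_rng(self.seed)
        self.model_ = MobileViTv2(width=self.width, num_classes=self.n_classes,
                                  seed=self.seed)
        eval_data = None
        if eval_set is not None:
            Xv, yv = eval_set
            eval_data = (self._encode(np.asarray(Xv, dtype=np.float32), self.scaler_),
                         np.asarray(yv, dtype=np.int64))
        self.history_ = _train_loop(
            self.model_, Xp, y, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.learning_rate, momentum=self.momentum, nesterov=self.nesterov,
            weight_decay=self.weight_decay, optimizer=self.optimizer, rng=rng,
            eval_data=eval_data, verbose=self.verbose)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return _batched_forward(self.model_, self._encode(
            np.asarray(X, dtype=np.float32), self.scaler_))

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


class LateFusionClassifier(ClassifierMixin, BaseEstimator):
    """Weighted softmax-level fusion of up to three fitted cue branches.

    ``X`` is a mapping with keys ``"body"`` (N, 3, 60, 17) and/or
    ``"face"`` (N, 60, 68, 3); the joints and bones branches both read
    ``"body"``, the face branch reads ``"face"``.  Missing branches get
    weight zero.  ``weights="grid"`` searches {0.1..1.0}^3 on the fit
    data (or on ``eval_set`` when provided).
    """

    def __init__(self, joints=None, bones=None, face=None, weights=(1.0, 1.0, 1.0)):
        self.joints = joints
        self.bones = bones
        self.face = face
        self.weights = weights

    def _branch_probs(self, X, n: int) -> dict:
        probs = {}
        uniform = np.full((n, 6), 1.0 / 6)
        for name, est, key in (("joints", self.joints, "body"),
                               ("bones", self.bones, "body"),
                               ("face", self.face, "face")):
            probs[name] = est.predict_proba(X[key]) if est is not None else uniform
        return probs

    def _n_samples(self, X) -> int:
        for key in ("body", "face"):
            if key in X:
                return len(X[key])
        raise ValueError("X must contain 'body' and/or 'face' arrays")

    def fit(self, X, y, eval_set=None):
        y = np.asarray(y, dtype=np.int64)
        for est, key in ((self.joints, "body"), (self.bones, "body"),
                         (self.face, "face")):
            if est is not None and not hasattr(est, "model_"):
                est.fit(X[key], y)
        if isinstance(self.weights, str) and self.weights == "grid":
            Xs, ys = (eval_set if eval_set is not None else (X, y))
            probs = self._branch_probs(Xs, len(np.asarray(ys)))
            self.weights_, _ = grid_search_weights(
                probs["joints"], probs["bones"], probs["face"], ys)
        else:
            self.weights_ = tuple(float(w) for w in self.weights)
        active = [w for w, est in zip(self.weights_,
                                      (self.joints, self.bones, self.face))
                  if est is not None]
        if not any(active):
            raise ValueError("no branch with positive weight")
        self.classes_ = np.arange(6)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        probs = self._branch_probs(X, self._n_samples(X))
        w = [wi if est is not None else 0.0
             for wi, est in zip(self.weights_, (self.joints, self.bones, self.face))]
        scores, _ = fuse(probs["joints"], probs["bones"], probs["face"], w)
        return scores

    def predict_proba(self, X):
        scores = self.decision_function(X)
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.decision_function(X).argmax(axis=1)


def evaluate_branches(fused: LateFusionClassifier, X, y) -> dict:
    """Per-branch and fused metrics reports on one evaluation set."""
    y = np.asarray(y, dtype=np.int64)
    n = fused._n_samples(X)
    probs = fused._branch_probs(X, n)
    report = {}
    for name, est in (("joints", fused.joints), ("bones", fused.bones),
                      ("face", fused.face)):
        if est is not None:
            report[name] = evaluation_report(probs[name], y)
    report["fused"] = evaluation_report(fused.decision_function(X), y)
    report["weights"] = list(getattr(fused, "weights_", fused.weights))
    return report
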