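"""Run-directory orchestration: config-driven branch training and evaluation.

Each training run writes a self-contained directory: the resolved config
snapshot (YAML), a JSON-lines event log, per-epoch history, the final
checkpoint (arrays + config) and a metrics report, sufficient to
re-execute or audit the run.
"""

from __future__ import annotations

import json
import subprocess
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import (FaceActionClassifier, LateFusionClassifier,
                         SkeletonActionClassifier, evaluate_branches)
from .io import load_sample

__all__ = ["RunConfig", "load_manifest_arrays", "train_branch",
           "load_checkpoint", "evaluate_run"]


@dataclass
class RunConfig:
    """Training configuration; defaults follow the reference recipe
    (SGD, Nesterov momentum 0.9, lr 0.01, weight decay 1e-4, batch 8,
    100 epochs, cross-entropy)."""

    branch: str = "joints"                 # joints | bones | face
    graph_variant: str = "our"
    use_msst: bool = True
    use_mae: bool = True
    mae_stage: int = 1
    base_channels: int = 64
    face_width: float = 1.5
    face_input_size: int = 256
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 0.01
    momentum: float = 0.9
    nesterov: bool = True
    weight_decay: float = 1e-4
    optimizer: str = "sgd"
    n_classes: int = 6
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self):
        if self.branch not in ("joints", "bones", "face"):
            raise ValueError(f"unknown branch {self.branch!r}")
        return self

    def make_estimator(self, verbose: int = 0):
        if self.branch == "face":
            return FaceActionClassifier(
                width=self.face_width, input_size=self.face_input_size,
                epochs=self.epochs, batch_size=self.batch_size,
                learning_rate=self.learning_rate, momentum=self.momentum,
                nesterov=self.nesterov, weight_decay=self.weight_decay,
                optimizer=self.optimizer, n_classes=self.n_classes,
                seed=self.seed, verbose=verbose)
        return SkeletonActionClassifier(
            branch=self.branch, graph_variant=self.graph_variant,
            base_channels=self.base_channels, use_msst=self.use_msst,
            use_mae=self.use_mae, mae_stage=self.mae_stage,
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, momentum=self.momentum,
            nesterov=self.nesterov, weight_decay=self.weight_decay,
            optimizer=self.optimizer, n_classes=self.n_classes,
            seed=self.seed, verbose=verbose)

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        extra = {k: doc.pop(k) for k in list(doc) if k not in known}
        return cls(**doc, extra=extra)


def _git_describe(cwd) -> str:
    try:
        out = subprocess.run(["git", "describe", "--always", "--dirty"],
                             cwd=cwd, capture_output=True, text=True, timeout=10)
        return out.stdout.strip() or "unknown"
    except Exception:
        return "unknown"


def load_manifest_arrays(manifest_path):
    """Load a generated dataset: returns dict with per-split body/face/label
    arrays keyed 'train' and 'val'."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    out = {}
    for split, sub in df.groupby("split"):
        bodies, faces, labels = [], [], []
        for _, row in sub.iterrows():
            body, face, label = load_sample(root / row["path"])
            bodies.append(body.data)
            faces.append(face.data)
            labels.append(label)
        out[split] = {"body": np.stack(bodies), "face": np.stack(faces),
                      "label": np.array(labels, dtype=np.int64)}
    return out


class _JsonlLogger:
    def __init__(self, path):
        self.path = Path(path)

    def log(self, event: str, **payload):
        rec = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event, **payload}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def train_branch(config: RunConfig, manifest_path, run_dir, verbose: int = 0):
    """Train one branch on a manifest dataset; write a run directory.

    Returns ``(estimator, metrics)``.  Raises a config error when the
    branch does not match the data (e.g. face branch without face arrays).
    """
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger = _JsonlLogger(run_dir / "log.jsonl")
    snapshot = {**asdict(config), "manifest": str(manifest_path),
                "git": _git_describe(Path(manifest_path).parent)}
    with open(run_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=False)
    data = load_manifest_arrays(manifest_path)
    if "train" not in data:
        raise ValueError("manifest has no train split")
    key = "face" if config.branch == "face" else "body"
    train, val = data["train"], data.get("val")
    logger.log("start", branch=config.branch, n_train=len(train["label"]),
               n_val=0 if val is None else len(val["label"]))
    est = config.make_estimator(verbose=verbose)
    eval_set = (val[key], val["label"]) if val is not None else None
    est.fit(train[key], train["label"], eval_set=eval_set)
    for row in est.history_:
        logger.log("epoch", **row)
    pd.DataFrame(est.history_).to_csv(run_dir / "history.csv", index=False)
    metrics = {"final_train_loss": est.history_[-1]["loss"]}
    if val is not None:
        metrics["val_top1"] = float(
            (est.predict(val[key]) == val["label"]).mean() * 100)
    with open(run_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    _save_checkpoint(run_dir / "checkpoint.npz", config, est)
    logger.log("done", **metrics)
    return est, metrics


def _save_checkpoint(path, config: RunConfig, est):
    arrays = {f"param/{k}": v for k, v in est.model_.state_dict().items()}
    header = {"config": asdict(config)}
    if hasattr(est, "scaler_"):
        header["scaler"] = {"x_max": est.scaler_.x_max, "y_max": est.scaler_.y_max}
    np.savez_compressed(path, __header__=json.dumps(header), **arrays)


def load_checkpoint(path):
    """Rebuild a fitted estimator from a checkpoint file."""
    from .face import FaceScaler
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["__header__"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    config = RunConfig(**header["config"])
    est = config.make_estimator()
    if config.branch == "face":
        est.scaler_ = FaceScaler(**header["scaler"])
        from .mobilevit import MobileViTv2
        est.model_ = MobileViTv2(width=config.face_width,
                                 num_classes=config.n_classes, seed=config.seed)
    else:
        from .agcn import SkeletonBackbone
        from .graph import build_graph, partition_adjacency
        est.graph_ = build_graph(config.graph_variant)
        est.model_ = SkeletonBackbone(
            partition_adjacency(est.graph_), num_classes=config.n_classes,
            base_channels=config.base_channels, use_msst=config.use_msst,
            use_mae=config.use_mae, mae_stage=config.mae_stage, seed=config.seed)
    est.model_.load_state_dict(state)
    est.classes_ = np.arange(config.n_classes)
    return config, est


def evaluate_run(checkpoints: dict, manifest_path, weights=(1.0, 1.0, 1.0),
                 split: str = "val") -> dict:
    """Evaluate 1-3 branch checkpoints (keys joints/bones/face) with fusion."""
    ests = {}
    for name, path in checkpoints.items():
        if name not in ("joints", "bones", "face"):
            raise ValueError(f"unknown branch key {name!r}")
        config, est = load_checkpoint(path)
        if config.branch != name:
            raise ValueError(f"checkpoint {path} holds branch "
                             f"{config.branch!r}, expected {name!r}")
        ests[name] = est
    data = load_manifest_arrays(manifest_path)
    if split not in data:
        raise ValueError(f"manifest has no {split!r} split")
    d = data[split]
    fused = LateFusionClassifier(joints=ests.get("joints"), bones=ests.get("bones"),
                                 face=ests.get("face"), weights=weights)
    fused.weights_ = tuple(float(w) for w in weights)
    fused.classes_ = np.arange(6)
    X = {"body": d["body"], "face": d["face"]}
    return evaluate_branches(fused, X, d["label"])
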