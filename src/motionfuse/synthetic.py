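"""Synthetic six-class behaviour sequences for desk-scale training and tests.

Generates labelled body (3, 60, 17) and face (60, 68, 3) keypoint
sequences that emulate the six action states observed during a
continuous-performance attention test:

1. head turning — a sudden lateral rotation burst of the head cluster
   after a random onset frame;
2. body shaking — irregular lateral oscillation of the torso with a
   jittered period;
3. resting head on hand — one wrist travels to the head region and the
   pose then stays quasi-static;
4. inattentive facial expression — the body stays still while mouth and
   brow landmarks (and the two mouth-corner body joints) burst-displace;
5. lying on the desk — head and shoulders drift monotonically down to
   desk level, then rest;
6. no significant symptoms — small isotropic jitter only.

All sequences start from a canonical seated template pose stored as a
versioned fixture file.  Coordinate noise and confidence dropout emulate
pose-estimator imperfections: dropped cells get a confidence below the
repair threshold so the interpolation stage has realistic work to do.

The generator is deterministic given the spec's seed; no global RNG
state is touched.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import JOINT_NAMES
from .io import (FaceSequence, SkeletonSequence, save_sample, write_manifest,
                 DEFAULT_CONF_THRESHOLD)

__all__ = ["SyntheticSpec", "load_template", "generate_sample",
           "generate_arrays", "generate_dataset", "CLASS_NAMES"]

CLASS_NAMES = {
    1: "turning_head",
    2: "shaking_body",
    3: "resting_head_on_hand",
    4: "inattentive_expression",
    5: "lying_on_desk",
    6: "no_significant_symptoms",
}

_J = {name: i for i, name in enumerate(JOINT_NAMES)}
_HEAD_JOINTS = [_J[n] for n in ("nose", "left_eye", "right_eye", "left_ear",
                                "right_ear", "left_mouth", "right_mouth", "head_top")]
_TORSO_JOINTS = [_J[n] for n in ("neck", "left_shoulder", "right_shoulder",
                                 "left_elbow", "right_elbow", "left_wrist", "right_wrist")]
_SHOULDERS = [_J["left_shoulder"], _J["right_shoulder"]]
_MOUTH_JOINTS = [_J["left_mouth"], _J["right_mouth"]]
_MOUTH_LANDMARKS = list(range(48, 68))
_BROW_LANDMARKS = list(range(17, 27))


@dataclass
class SyntheticSpec:
    """Archetype parameters for one generated sample.

    Amplitudes are pixels on the 1280x720 template frame; the onset frame
    for sudden movements is drawn uniformly from ``onset_range``.
    """

    class_id: int
    amplitude: float | None = None      # class default when None
    period: float = 12.0                # frames, class-2 oscillation
    onset_range: tuple = (5, 40)
    noise_sd: float = 2.0               # coordinate noise, pixels
    dropout: float = 0.05               # P(confidence forced below threshold)
    seed: int = 0

    #: per-class default motion amplitude (pixels)
    CLASS_AMPLITUDES = {1: 45.0, 2: 25.0, 3: 55.0, 4: 9.0, 5: 230.0, 6: 0.0}

    def __post_init__(self):
        if self.class_id not in CLASS_NAMES:
            raise ValueError(f"unknown class id {self.class_id} (expected 1..6)")
        if self.amplitude is None:
            self.amplitude = self.CLASS_AMPLITUDES[self.class_id]
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def load_template() -> dict:
    """The canonical seated pose: joints (17, 2), landmarks (68, 2), frame size."""
    ref = importlib.resources.files("motionfuse.data") / "seated_template.yaml"
    doc = yaml.safe_load(ref.read_text())
    joints = np.array([doc["joints"][name] for name in JOINT_NAMES], dtype=np.float64)
    landmarks = np.array(doc["face_landmarks"], dtype=np.float64)
    return {"joints": joints, "landmarks": landmarks,
            "image_size": tuple(doc["image_size"]),
            "desk_level_y": float(doc["desk_level_y"])}


def _ramp(T: int, onset: int, length: int) -> np.ndarray:
    """0 before onset, linear rise over `length` frames, 1 after."""
    t = np.arange(T, dtype=np.float64)
    return np.clip((t - onset) / max(length, 1), 0.0, 1.0)


def _apply_class_motion(body, face, spec: SyntheticSpec, rng, template):
    """Write the class archetype into (2, T, 17) body xy and (T, 68, 2) face xy."""
    T = body.shape[1]
    a = spec.amplitude
    onset = int(rng.integers(spec.onset_range[0], spec.onset_range[1] + 1))
    side = 1.0 if rng.random() < 0.5 else -1.0
    cid = spec.class_id

    if cid == 1:
        # sudden lateral head rotation: shared x-shift of the head cluster,
        # with a slight counter-shift of ears to mimic yaw foreshortening
        r = _ramp(T, onset, 6) * side
        body[0, :, _HEAD_JOINTS] += a * r
        face[:, :, 0] += 0.9 * a * r[:, None]
    elif cid == 2:
        # irregular torso oscillation: per-cycle jittered period and phase
        phase = np.zeros(T)
        step = 2 * np.pi / spec.period
        for t in range(1, T):
            phase[t] = phase[t - 1] + step * (1.0 + 0.35 * rng.standard_normal())
        wave = np.sin(phase)
        body[0, :, _TORSO_JOINTS] += a * wave
        body[0, :, _HEAD_JOINTS] += 0.8 * a * wave
        body[0, :, [_J["left_hip"], _J["right_hip"]]] += 0.25 * a * wave
        face[:, :, 0] += 0.8 * a * wave[:, None]
    elif cid == 3:
        # wrist travels to the ear region, elbow follows, then quasi-static
        wrist = _J["left_wrist"] if side > 0 else _J["right_wrist"]
        elbow = _J["left_elbow"] if side > 0 else _J["right_elbow"]
        ear = _J["left_ear"] if side > 0 else _J["right_ear"]
        r = _ramp(T, onset, 10)
        target = template["joints"][ear] + np.array([10.0 * side, 18.0])
        delta = target - template["joints"][wrist]
        body[0, :, wrist] += delta[0] * r
        body[1, :, wrist] += delta[1] * r
        body[0, :, elbow] += 0.5 * delta[0] * r
        body[1, :, elbow] += 0.5 * delta[1] * r
        tilt = 8.0 * side * r
        body[0, :, _HEAD_JOINTS] += tilt
        face[:, :, 0] += tilt[:, None]
    elif cid == 4:
        # facial bursts: mouth opens / brows raise in 2-3 bursts; the two
        # mouth-corner body joints move with the outer mouth corners
        n_bursts = int(rng.integers(2, 4))
        starts = rng.integers(spec.onset_range[0], T - 10, n_bursts)
        envelope = np.zeros(T)
        for s in starts:
            t = np.arange(T)
            envelope += np.exp(-0.5 * ((t - s - 4) / 3.0) ** 2)
        envelope = np.clip(envelope, 0, 1)
        face[:, _MOUTH_LANDMARKS, 1] += a * envelope[:, None]
        face[:, _BROW_LANDMARKS, 1] -= 0.7 * a * envelope[:, None]
        body[1, :, _MOUTH_JOINTS] += a * envelope
    elif cid == 5:
        # monotone head+shoulder descent to desk level, then static
        r = _ramp(T, onset, 15)
        head_drop = min(a, template["desk_level_y"] - template["joints"][_J["nose"]][1]
                        + 160.0)
        body[1, :, _HEAD_JOINTS] += head_drop * r
        body[1, :, _J["neck"]] += 0.8 * head_drop * r
        body[1, :, _SHOULDERS] += 0.35 * head_drop * r
        # slumping forward also shifts the head cluster laterally a little
        body[0, :, _HEAD_JOINTS] += 25.0 * side * r
        face[:, :, 1] += head_drop * r[:, None]
        face[:, :, 0] += 25.0 * side * r[:, None]
    # class 6: no archetype motion
    return onset


def generate_sample(spec: SyntheticSpec):
    """One labelled sample: (SkeletonSequence, FaceSequence, 0-based label)."""
    rng = np.random.default_rng(spec.seed)
    template = load_template()
    T = 60
    body = np.repeat(template["joints"].T[:, None, :], T, axis=1)   # (2, T, 17)
    face = np.repeat(template["landmarks"][None], T, axis=0)        # (T, 68, 2)
    onset = _apply_class_motion(body, face, spec, rng, template)

    if spec.noise_sd > 0:
        body += rng.normal(0.0, spec.noise_sd, body.shape)
        face += rng.normal(0.0, spec.noise_sd, face.shape)

    w, h = template["image_size"]
    body[0] = np.clip(body[0], 0, w - 1)
    body[1] = np.clip(body[1], 0, h - 1)
    face[..., 0] = np.clip(face[..., 0], 0, w - 1)
    face[..., 1] = np.clip(face[..., 1], 0, h - 1)

    conf_body = np.clip(rng.normal(0.9, 0.04, (T, 17)), 0.0, 1.0)
    conf_face = np.clip(rng.normal(0.9, 0.04, (T, 68)), 0.0, 1.0)
    if spec.dropout > 0:
        # dropped cells fall below the repair threshold
        drop_b = rng.random((T, 17)) < spec.dropout
        drop_f = rng.random((T, 68)) < spec.dropout
        conf_body[drop_b] = rng.uniform(0.0, DEFAULT_CONF_THRESHOLD / 2,
                                        int(drop_b.sum()))
        conf_face[drop_f] = rng.uniform(0.0, DEFAULT_CONF_THRESHOLD / 2,
                                        int(drop_f.sum()))

    body_full = np.concatenate([body, conf_body[None]], axis=0).astype(np.float32)
    face_full = np.concatenate([face, conf_face[..., None]], axis=2).astype(np.float32)
    meta = {"class_id": spec.class_id, "class_name": CLASS_NAMES[spec.class_id],
            "onset": onset, **{k: v for k, v in asdict(spec).items()
                               if k not in ("class_id",)}}
    skeleton = SkeletonSequence(body_full, metadata=meta)
    return skeleton, FaceSequence(face_full), spec.class_id - 1


def generate_arrays(n_per_class: int, seed: int = 0, **spec_kwargs):
    """In-memory dataset: (bodies (N,3,60,17), faces (N,60,68,3), labels (N,)).

    Sample seeds are drawn from one seeded generator so the dataset is
    reproducible as a whole.
    """
    master = np.random.default_rng(seed)
    bodies, faces, labels = [], [], []
    for class_id in range(1, 7):
        for _ in range(n_per_class):
            spec = SyntheticSpec(class_id=class_id,
                                 seed=int(master.integers(0, 2**31 - 1)),
                                 **spec_kwargs)
            b, f, y = generate_sample(spec)
            bodies.append(b.data)
            faces.append(f.data)
            labels.append(y)
    return np.stack(bodies), np.stack(faces), np.array(labels, dtype=np.int64)


def generate_dataset(out_dir, n_per_class: int, seed: int = 0,
                     train_fraction: float = 0.7, **spec_kwargs) -> pd.DataFrame:
    """Write a stratified dataset to disk: one .npz archive per sample plus
    a manifest CSV carrying each sample's spec parameters and split."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    for class_id in range(1, 7):
        n_train = int(round(train_fraction * n_per_class))
        for i in range(n_per_class):
            spec = SyntheticSpec(class_id=class_id,
                                 seed=int(master.integers(0, 2**31 - 1)),
                                 **spec_kwargs)
            body, face, label = generate_sample(spec)
            sample_id = f"c{class_id}_{i:04d}"
            path = out_dir / f"{sample_id}.npz"
            save_sample(path, body, face, label)
            rows.append({
                "sample_id": sample_id, "label": label, "class_id": class_id,
                "split": "train" if i < n_train else "val",
                "path": path.name, "padded": body.padded,
                "seed": spec.seed, "amplitude": spec.amplitude,
                "noise_sd": spec.noise_sd, "dropout": spec.dropout,
            })
    return write_manifest(out_dir / "manifest.csv", rows)
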