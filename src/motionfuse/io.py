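"""Reading AlphaPose-style keypoint JSON and assembling fixed-length sequences.

A detection file is a JSON list of per-frame records in the COCO-results
dialect: each record carries a frame identifier (``image_id`` like
``"12.jpg"`` or an integer ``idx``/``frame_id``), a flat ``keypoints``
triplet list ``[x1, y1, s1, x2, y2, s2, ...]`` for the 17 body joints and,
when face detection was enabled, a flat ``face_keypoints`` list for the 68
facial landmarks.

Body sequences are ``(3, T, 17)`` arrays with channel order ``(x, y, s)``;
face sequences are ``(T, 68, 3)``.  Coordinates are pixels with the origin
at the top-left; frame and joint indices are 0-based.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .graph import JOINT_NAMES, SkeletonGraph

__all__ = [
    "Keypoint", "FrameRecord", "SkeletonSequence", "FaceSequence",
    "read_alphapose_json", "assemble_sequence", "interpolate_missing",
    "joints_to_bones", "save_sample", "load_sample", "write_manifest",
    "DEFAULT_CONF_THRESHOLD", "NUM_BODY_JOINTS", "NUM_FACE_LANDMARKS",
]

NUM_BODY_JOINTS = 17
NUM_FACE_LANDMARKS = 68
DEFAULT_FRAME_COUNT = 60
#: Detections with confidence below this are treated as missing (repairable).
DEFAULT_CONF_THRESHOLD = 0.3


class Keypoint(NamedTuple):
    x: float
    y: float
    s: float


@dataclass
class FrameRecord:
    """One frame's detections: 17 body keypoints, optionally 68 face landmarks."""

    frame_index: int
    body: list
    face: list | None = None


@dataclass
class SkeletonSequence:
    """Body keypoints, shape (3, T, 17), channels (x, y, s)."""

    data: np.ndarray
    layout_id: str = "upper17"
    padded: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != 3 \
                or self.data.shape[2] != NUM_BODY_JOINTS:
            raise ValueError(f"SkeletonSequence must be (3, T, {NUM_BODY_JOINTS}), "
                             f"got {self.data.shape}")
        s = self.data[2]
        if not np.isfinite(self.data).all():
            raise ValueError("SkeletonSequence contains non-finite values")
        if s.min() < 0 or s.max() > 1:
            raise ValueError("confidence channel must lie in [0, 1]")

    @property
    def frame_count(self) -> int:
        return self.data.shape[1]


@dataclass
class FaceSequence:
    """Facial landmarks, shape (T, 68, 3), last axis (x, y, s)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[1:] != (NUM_FACE_LANDMARKS, 3):
            raise ValueError(f"FaceSequence must be (T, {NUM_FACE_LANDMARKS}, 3), "
                             f"got {self.data.shape}")
        s = self.data[..., 2]
        if not np.isfinite(self.data).all():
            raise ValueError("FaceSequence contains non-finite values")
        if s.min() < 0 or s.max() > 1:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def frame_count(self) -> int:
        return self.data.shape[0]


def _frame_index(record: dict, position: int) -> int:
    for key in ("idx", "frame_id", "frame_index"):
        if key in record:
            return int(record[key])
    if "image_id" in record:
        m = re.search(r"(\d+)", str(record["image_id"]))
        if m:
            return int(m.group(1))
    raise ValueError(f"record {position}: no frame identifier "
                     "(expected idx/frame_id/image_id)")


def _triplets(flat, n_expected, what, position) -> list:
    flat = list(flat)
    if len(flat) != 3 * n_expected:
        raise ValueError(f"record {position}: {what} has {len(flat)} values, "
                         f"expected {3 * n_expected} (={n_expected} triplets)")
    pts = []
    for i in range(n_expected):
        x, y, s = flat[3 * i:3 * i + 3]
        pts.append(Keypoint(float(x), float(y), float(np.clip(s, 0.0, 1.0))))
    return pts


def read_alphapose_json(path) -> list:
    """Parse an AlphaPose COCO-dialect results file into frame records.

    Returns records ordered by frame index.  Raises ``FileNotFoundError``
    for a missing file, ``ValueError`` for malformed JSON (naming the
    offending record) and for an empty detection list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"keypoint file not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a JSON list of detections")
    if len(raw) == 0:
        raise ValueError(f"{path}: empty detection list (no frames)")
    frames = []
    for pos, record in enumerate(raw):
        if not isinstance(record, dict) or "keypoints" not in record:
            raise ValueError(f"{path}: record {pos} malformed (no 'keypoints')")
        fi = _frame_index(record, pos)
        body = _triplets(record["keypoints"], NUM_BODY_JOINTS, "keypoints", pos)
        face = None
        if record.get("face_keypoints") is not None:
            face = _triplets(record["face_keypoints"], NUM_FACE_LANDMARKS,
                             "face_keypoints", pos)
        frames.append(FrameRecord(frame_index=fi, body=body, face=face))
    frames.sort(key=lambda fr: fr.frame_index)
    return frames


def assemble_sequence(frames, target_T: int = DEFAULT_FRAME_COUNT):
    """Stack frame records into fixed-length body and face sequences.

    Longer inputs are truncated to the first ``target_T`` frames; shorter
    inputs are padded by repeating the last frame (recorded in metadata
    and the ``padded`` flag).  Frames lacking face landmarks contribute
    zero-confidence landmarks at the face centroid proxy (0, 0).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("assemble_sequence: no frames")
    for fr in frames:
        if len(fr.body) != NUM_BODY_JOINTS:
            raise ValueError(f"frame {fr.frame_index}: expected {NUM_BODY_JOINTS} "
                             f"body joints, got {len(fr.body)}")
    padded = len(frames) < target_T
    if padded:
        frames = frames + [frames[-1]] * (target_T - len(frames))
    frames = frames[:target_T]

    body = np.zeros((3, target_T, NUM_BODY_JOINTS), dtype=np.float32)
    face = np.zeros((target_T, NUM_FACE_LANDMARKS, 3), dtype=np.float32)
    for t, fr in enumerate(frames):
        arr = np.asarray(fr.body, dtype=np.float32)       # (17, 3)
        body[:, t, :] = arr.T
        if fr.face is not None:
            face[t] = np.asarray(fr.face, dtype=np.float32)
    meta = {"source_frames": len(set(fr.frame_index for fr in frames)), "padded": padded}
    return (SkeletonSequence(body, padded=padded, metadata=meta), FaceSequence(face))


def interpolate_missing(seq: SkeletonSequence,
                        conf_threshold: float = DEFAULT_CONF_THRESHOLD) -> SkeletonSequence:
    """Repair low-confidence keypoints by temporal linear interpolation.

    For every (joint, frame) with confidence below the threshold, x and y
    are linearly interpolated between the nearest flanking frames of the
    same joint at or above threshold; leading/trailing gaps copy the
    nearest valid frame.  Repaired confidences are set to the threshold.
    A joint that never reaches the threshold is left as-is (warned).
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must lie in [0, 1]")
    data = seq.data.copy()
    T = data.shape[1]
    times = np.arange(T)
    for j in range(data.shape[2]):
        s = data[2, :, j]
        valid = s >= conf_threshold
        if valid.all():
            continue
        if not valid.any():
            warnings.warn(f"joint {j} ({JOINT_NAMES[j]}): no frame reaches "
                          f"confidence {conf_threshold}; left unrepaired")
            continue
        vt = times[valid]
        for c in (0, 1):
            data[c, ~valid, j] = np.interp(times[~valid], vt, data[c, valid, j])
        data[2, ~valid, j] = conf_threshold
    return SkeletonSequence(data, layout_id=seq.layout_id, padded=seq.padded,
                            metadata={**seq.metadata, "interpolated": True})


def joints_to_bones(seq: SkeletonSequence, graph: SkeletonGraph) -> SkeletonSequence:
    """Derive the bones stream: per-frame child-minus-parent vectors.

    The root joint's bone is the zero vector; bone confidence is the
    minimum of the child and parent confidences.  Output shape equals
    the input shape.
    """
    if graph.num_joints != seq.data.shape[2]:
        raise ValueError(f"layout mismatch: sequence has {seq.data.shape[2]} joints, "
                         f"graph has {graph.num_joints}")
    data = seq.data
    bones = np.zeros_like(data)
    for child, parent in graph.parents.items():
        bones[:2, :, child] = data[:2, :, child] - data[:2, :, parent]
        bones[2, :, child] = np.minimum(data[2, :, child], data[2, :, parent])
    root = graph.center_index
    bones[:2, :, root] = 0.0
    bones[2, :, root] = data[2, :, root]
    return SkeletonSequence(bones, layout_id=seq.layout_id, padded=seq.padded,
                            metadata={**seq.metadata, "stream": "bones"})


# -- sample archives ----------------------------------------------------

def save_sample(path, body: SkeletonSequence, face: FaceSequence, label: int,
                metadata: dict | None = None):
    """Write one sample as a compressed array archive (.npz)."""
    np.savez_compressed(
        path, body=body.data, face=face.data, label=np.int64(label),
        padded=np.bool_(body.padded),
        metadata=json.dumps({**body.metadata, **(metadata or {})}),
    )


def load_sample(path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["metadata"]))
        body = SkeletonSequence(z["body"], padded=bool(z["padded"]), metadata=meta)
        face = FaceSequence(z["face"])
        label = int(z["label"])
    return body, face, label


def write_manifest(path, rows) -> pd.DataFrame:
    """Write the sample manifest CSV (sample_id, label, source, pad flag, ...)."""
    df = pd.DataFrame(rows)
    required = {"sample_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest rows need columns {sorted(required)}")
    df.to_csv(path, index=False)
    return df
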