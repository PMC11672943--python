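"""Facial-landmark sequence -> pseudo-color image encoding and classification.

A 60-frame, 68-landmark face sequence is encoded as a 68x60 RGB image:
row j is landmark j, column i is frame i, and the three channels hold the
coordinates and detection confidence scaled to [0, 255]:

    X' = round(255 * X / X_max),  Y' = round(255 * Y / Y_max),  S' = round(255 * S)

with ``X_max, Y_max`` the coordinate maxima observed on the training
split (fitting the scaler on the training split only avoids leakage; a
whole-dataset fit is available for strict replication).  Rounding is
half-up, then clamped.  The image is classified by the MobileViTv2-style
backbone after bilinear resize to its input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .io import FaceSequence, NUM_FACE_LANDMARKS
from .mobilevit import MobileViTv2

__all__ = [
    "FaceScaler", "FaceImage", "fit_scaler", "face_to_image", "image_to_sequence",
    "save_png", "load_png", "prepare_backbone_input", "classify_face_image",
    "read_landmark_csv", "arousal_to_label",
]

IMAGE_ROWS = NUM_FACE_LANDMARKS  # 68 landmarks
IMAGE_COLS = 60                  # frames


@dataclass(frozen=True)
class FaceScaler:
    """Dataset-wide coordinate maxima used to normalize landmark pixels."""

    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > 0 and self.y_max > 0):
            raise ValueError("scaler maxima must be positive")


@dataclass
class FaceImage:
    """68x60x3 uint8 image (rows=landmarks, cols=frames, channels=(X',Y',S'))."""

    pixels: np.ndarray
    scaler: FaceScaler

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_ROWS, IMAGE_COLS, 3):
            raise ValueError(f"FaceImage must be {IMAGE_ROWS}x{IMAGE_COLS}x3, "
                             f"got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)


def fit_scaler(sequences) -> FaceScaler:
    """Coordinate maxima over all frames, landmarks and (training) samples."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("fit_scaler needs at least one sequence")
    x_max = max(float(s.data[..., 0].max()) for s in sequences)
    y_max = max(float(s.data[..., 1].max()) for s in sequences)
    if x_max <= 0 or y_max <= 0:
        raise ValueError(f"degenerate scaler (x_max={x_max}, y_max={y_max}); "
                         "are the coordinates all zero?")
    return FaceScaler(x_max=x_max, y_max=y_max)


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5)


def face_to_image(seq: FaceSequence, scaler: FaceScaler) -> FaceImage:
    """Encode a (60, 68, 3) landmark sequence as a 68x60 pseudo-color image."""
    data = seq.data
    if data.shape[0] != IMAGE_COLS:
        raise ValueError(f"expected {IMAGE_COLS} frames, got {data.shape[0]}")
    scaled = np.empty_like(data, dtype=np.float64)
    scaled[..., 0] = data[..., 0] / scaler.x_max * 255.0
    scaled[..., 1] = data[..., 1] / scaler.y_max * 255.0
    scaled[..., 2] = data[..., 2] * 255.0
    pixels = np.clip(_round_half_up(scaled), 0, 255).astype(np.uint8)
    # (frame, landmark, channel) -> (landmark row, frame column, channel)
    return FaceImage(pixels=pixels.transpose(1, 0, 2), scaler=scaler)


def image_to_sequence(img: FaceImage) -> FaceSequence:
    """De-quantize an image back to a landmark sequence (inverse up to the
    8-bit rounding: coordinates agree within (X_max/510, Y_max/510, 1/510))."""
    px = img.pixels.astype(np.float64).transpose(1, 0, 2)
    data = np.empty_like(px, dtype=np.float32)
    data[..., 0] = px[..., 0] / 255.0 * img.scaler.x_max
    data[..., 1] = px[..., 1] / 255.0 * img.scaler.y_max
    data[..., 2] = px[..., 2] / 255.0
    return FaceSequence(data)


def save_png(img: FaceImage, path):
    Image.fromarray(img.pixels, mode="RGB").save(path, format="PNG")


def load_png(path, scaler: FaceScaler) -> FaceImage:
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return FaceImage(pixels=pixels, scaler=scaler)


def prepare_backbone_input(img: FaceImage, size: int = 256) -> np.ndarray:
    """Bilinear-resize to (size, size) and scale to [0, 1]; returns (3, size, size)."""
    pil = Image.fromarray(img.pixels, mode="RGB")
    resized = np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.float32)
    return (resized / 255.0).transpose(2, 0, 1)


def classify_face_image(img: FaceImage, model: MobileViTv2, size: int = 256) -> np.ndarray:
    """Logits for one image from a (fitted) backbone, in inference mode."""
    from .autodiff import Tensor
    x = Tensor(prepare_backbone_input(img, size)[None])
    was_training = model.training
    model.eval()
    try:
        logits = model(x)
    finally:
        model.train(was_training)
    return logits.data[0]


# -- AFEW-VA-style adapter ----------------------------------------------

def read_landmark_csv(path, n_frames: int = IMAGE_COLS) -> tuple:
    """Read a (frame, landmark_id, x, y[, arousal]) CSV into a FaceSequence.

    Landmark-only datasets carry no detection confidence; S is set to 1.
    Returns ``(sequence, mean_arousal)`` with ``mean_arousal`` None when
    the column is absent.
    """
    df = pd.read_csv(path)
    required = {"frame", "landmark_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV needs columns {sorted(required)}")
    frames = sorted(df["frame"].unique())
    data = np.zeros((n_frames, NUM_FACE_LANDMARKS, 3), dtype=np.float32)
    data[..., 2] = 1.0
    for t, f in enumerate(frames[:n_frames]):
        sub = df[df["frame"] == f]
        ids = sub["landmark_id"].to_numpy(dtype=int)
        if ids.min() < 0 or ids.max() >= NUM_FACE_LANDMARKS:
            raise ValueError(f"frame {f}: landmark_id out of range 0..67")
        data[t, ids, 0] = sub["x"].to_numpy(dtype=np.float32)
        data[t, ids, 1] = sub["y"].to_numpy(dtype=np.float32)
    if len(frames) < n_frames:            # pad by repeating the last frame
        data[len(frames):] = data[len(frames) - 1]
    arousal = float(df["arousal"].mean()) if "arousal" in df.columns else None
    return FaceSequence(data), arousal


def arousal_to_label(mean_arousal: float) -> int:
    """Three-bin video label from the mean arousal: <0 -> 0, [0,3] -> 1, >3 -> 2."""
    if mean_arousal < 0:
        return 0
    if mean_arousal <= 3:
        return 1
    return 2
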