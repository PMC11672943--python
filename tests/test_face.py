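"""Landmark-image codec, its backbone, and the arousal labeling adapter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionfuse import nn
from motionfuse.autodiff import Tensor
from motionfuse.face import (FaceImage, FaceScaler, arousal_to_label,
                             classify_face_image, face_to_image, fit_scaler,
                             image_to_sequence, load_png, read_landmark_csv,
                             save_png)
from motionfuse.io import FaceSequence
from motionfuse.mobilevit import MobileViTv2, make_divisible


def make_face_sequence(rng, x_hi=640.0, y_hi=480.0):
    data = np.stack([rng.uniform(0, x_hi, (60, 68)),
                     rng.uniform(0, y_hi, (60, 68)),
                     rng.uniform(0, 1, (60, 68))], axis=-1).astype(np.float32)
    return FaceSequence(data)


class TestScaler:
    def test_single_sequence_maxima(self, rng):
        seq = make_face_sequence(rng)
        seq.data[3, 10, 0] = 640.0
        seq.data[5, 20, 1] = 480.0
        scaler = fit_scaler([seq])
        assert scaler.x_max == 640.0 and scaler.y_max == 480.0

    def test_two_sequences_elementwise_max(self, rng):
        a = make_face_sequence(rng, 300, 500)
        b = make_face_sequence(rng, 600, 200)
        scaler = fit_scaler([a, b])
        assert scaler.x_max == max(a.data[..., 0].max(), b.data[..., 0].max())
        assert scaler.y_max == max(a.data[..., 1].max(), b.data[..., 1].max())

    def test_all_zero_coordinates_rejected(self):
        seq = FaceSequence(np.zeros((60, 68, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="degenerate"):
            fit_scaler([seq])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_scaler([])


class TestCodec:
    scaler = FaceScaler(x_max=640.0, y_max=480.0)

    def seq_with(self, x, y, s):
        data = np.zeros((60, 68, 3), dtype=np.float32)
        data[..., 0], data[..., 1], data[..., 2] = x, y, s
        return FaceSequence(data)

    def test_maximum_landmark_maps_to_white(self):
        img = face_to_image(self.seq_with(640.0, 480.0, 1.0), self.scaler)
        assert (img.pixels == 255).all()

    def test_zero_landmark_maps_to_black(self):
        img = face_to_image(self.seq_with(0.0, 0.0, 0.0), self.scaler)
        assert (img.pixels == 0).all()

    def test_half_maximum_rounds_half_up_to_128(self):
        img = face_to_image(self.seq_with(320.0, 240.0, 0.5), self.scaler)
        assert (img.pixels == 128).all()          # 127.5 rounds up

    def test_rows_are_landmarks_and_columns_frames(self, rng):
        seq = make_face_sequence(rng)
        seq.data[7, 33, 0] = 640.0                # frame 7, landmark 33
        img = face_to_image(seq, self.scaler)
        assert img.pixels[33, 7, 0] == 255
        assert img.pixels.shape == (68, 60, 3)

    def test_wrong_frame_count_rejected(self):
        bad = FaceSequence(np.zeros((30, 68, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="expected 60 frames"):
            face_to_image(bad, self.scaler)

    def test_invertible_up_to_quantization(self, rng):
        seq = make_face_sequence(rng)
        scaler = fit_scaler([seq])
        back = image_to_sequence(face_to_image(seq, scaler))
        err = np.abs(back.data - seq.data)
        assert err[..., 0].max() <= scaler.x_max / 510 + 1e-4
        assert err[..., 1].max() <= scaler.y_max / 510 + 1e-4
        assert err[..., 2].max() <= 1 / 510 + 1e-4

    @given(st.floats(0, 600), st.floats(0, 600))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_coordinates(self, x1, x2):
        lo, hi = sorted((x1, x2))
        a = face_to_image(self.seq_with(lo, 0, 0), self.scaler).pixels[0, 0, 0]
        b = face_to_image(self.seq_with(hi, 0, 0), self.scaler).pixels[0, 0, 0]
        assert b >= a

    def test_png_roundtrip_is_bit_exact(self, rng, tmp_path):
        seq = make_face_sequence(rng)
        img = face_to_image(seq, self.scaler)
        save_png(img, tmp_path / "f.png")
        back = load_png(tmp_path / "f.png", self.scaler)
        assert np.array_equal(back.pixels, img.pixels)


class TestBackbone:
    def test_reference_width_parameter_budget(self):
        model = MobileViTv2(width=1.5, num_classes=1000)
        assert abs(nn.count_parameters(model) / 1e6 - 10.6) < 0.05

    def test_head_size_follows_class_count(self):
        base = MobileViTv2(width=0.5, num_classes=6, seed=0)
        three = MobileViTv2(width=0.5, num_classes=3, seed=0)
        diff = nn.count_parameters(base) - nn.count_parameters(three)
        assert diff == 3 * base.feature_dim + 3

    def test_identical_images_give_identical_logits_in_eval(self, rng):
        model = MobileViTv2(width=0.25, num_classes=6, seed=0)
        scaler = FaceScaler(x_max=640.0, y_max=480.0)
        img = face_to_image(make_face_sequence(rng), scaler)
        a = classify_face_image(img, model, size=64)
        b = classify_face_image(img, model, size=64)
        assert np.array_equal(a, b)
        assert np.isfinite(a).all()
        p = np.exp(a - a.max())
        assert np.isclose((p / p.sum()).sum(), 1.0, atol=1e-6)

    def test_make_divisible_matches_width_recipe(self):
        assert [make_divisible(v * 1.5, d) for v, d in
                ((64, 16), (128, 8), (256, 8), (384, 8), (512, 8))] == \
            [96, 192, 384, 576, 768]


class TestArousalAdapter:
    @pytest.mark.parametrize("mean,label", [
        (-2.5, 0), (-0.001, 0), (0.0, 1), (1.7, 1), (3.0, 1), (3.001, 2), (8.0, 2)])
    def test_three_bin_labeling(self, mean, label):
        assert arousal_to_label(mean) == label

    def test_landmark_csv_parsed_with_unit_confidence(self, tmp_path, rng):
        import pandas as pd
        rows = []
        for t in range(3):
            for j in range(68):
                rows.append({"frame": t, "landmark_id": j,
                             "x": float(rng.uniform(0, 100)),
                             "y": float(rng.uniform(0, 100)),
                             "arousal": 2.0 + t})
        path = tmp_path / "lm.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        seq, arousal = read_landmark_csv(path)
        assert seq.data.shape == (60, 68, 3)
        assert (seq.data[..., 2] == 1.0).all()
        assert arousal == pytest.approx(3.0)
        # short clips pad by repeating the last frame
        assert np.array_equal(seq.data[3], seq.data[2])
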