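"""Parsing, assembly, repair and the bones stream."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_alphapose_records
from motionfuse.graph import build_graph
from motionfuse.io import (FaceSequence, SkeletonSequence, assemble_sequence,
                           interpolate_missing, joints_to_bones, load_sample,
                           read_alphapose_json, save_sample)


def write_json(tmp_path, payload, name="poses.json"):
    path = tmp_path / name
    path.write_text(json.dumps(payload))
    return path


class TestReadAlphaposeJson:
    def test_two_frame_fixture_yields_two_records_of_17_keypoints(self, tmp_path, rng):
        path = write_json(tmp_path, make_alphapose_records(2, rng=rng))
        frames = read_alphapose_json(path)
        assert len(frames) == 2
        assert all(len(fr.body) == 17 for fr in frames)

    def test_keypoint_triplet_parsed_as_x_y_confidence(self, tmp_path):
        rec = {"image_id": "0.jpg", "keypoints": [12.0, 34.0, 0.9] + [0.0] * 48}
        frames = read_alphapose_json(write_json(tmp_path, [rec]))
        kp = frames[0].body[0]
        assert (kp.x, kp.y, kp.s) == (12.0, 34.0, 0.9)

    def test_frames_ordered_by_frame_index(self, tmp_path, rng):
        records = make_alphapose_records(3, rng=rng)
        frames = read_alphapose_json(write_json(tmp_path, records[::-1]))
        assert [fr.frame_index for fr in frames] == [0, 1, 2]

    def test_face_triplets_attached_when_present(self, tmp_path, rng):
        path = write_json(tmp_path, make_alphapose_records(2, with_face=True, rng=rng))
        frames = read_alphapose_json(path)
        assert all(len(fr.face) == 68 for fr in frames)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_alphapose_json(tmp_path / "absent.json")

    def test_empty_list_raises_empty_input_error(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            read_alphapose_json(write_json(tmp_path, []))

    def test_malformed_record_names_offending_index(self, tmp_path, rng):
        records = make_alphapose_records(2, rng=rng)
        records[1]["keypoints"] = records[1]["keypoints"][:30]
        with pytest.raises(ValueError, match="record 1"):
            read_alphapose_json(write_json(tmp_path, records))

    def test_invalid_json_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="not valid JSON"):
            read_alphapose_json(path)


class TestAssembleSequence:
    def test_sixty_frames_yield_canonical_shapes(self, tmp_path, rng):
        frames = read_alphapose_json(
            write_json(tmp_path, make_alphapose_records(60, with_face=True, rng=rng)))
        body, face = assemble_sequence(frames, target_T=60)
        assert body.data.shape == (3, 60, 17)
        assert face.data.shape == (60, 68, 3)
        assert not body.padded

    def test_single_frame_padded_by_repetition(self, tmp_path, rng):
        frames = read_alphapose_json(
            write_json(tmp_path, make_alphapose_records(1, rng=rng)))
        body, _ = assemble_sequence(frames, target_T=60)
        assert body.padded
        assert np.allclose(body.data, body.data[:, :1, :])

    def test_overlong_input_truncated_to_first_target_frames(self, tmp_path, rng):
        frames = read_alphapose_json(
            write_json(tmp_path, make_alphapose_records(75, rng=rng)))
        body, _ = assemble_sequence(frames, target_T=60)
        full, _ = assemble_sequence(frames, target_T=75)
        assert np.array_equal(body.data, full.data[:, :60, :])

    def test_wrong_joint_count_names_frame(self, tmp_path, rng):
        frames = read_alphapose_json(
            write_json(tmp_path, make_alphapose_records(2, rng=rng)))
        frames[1].body = frames[1].body[:10]
        with pytest.raises(ValueError, match="frame 1"):
            assemble_sequence(frames, target_T=60)


class TestInterpolateMissing:
    def make_seq(self, coords, confs):
        """(T,) per-joint scaffolding for joint 0; other joints fully valid."""
        T = len(coords)
        data = np.ones((3, T, 17), dtype=np.float32)
        data[0, :, 0] = coords
        data[1, :, 0] = coords
        data[2, :, 0] = confs
        return SkeletonSequence(data)

    def test_no_point_below_threshold_is_identity(self):
        seq = self.make_seq([0.0, 1.0, 2.0], [0.9, 0.9, 0.9])
        out = interpolate_missing(seq, 0.3)
        assert np.array_equal(out.data, seq.data)

    def test_midpoint_linear_interpolation_by_hand(self):
        seq = self.make_seq([0.0, 99.0, 2.0], [0.9, 0.0, 0.9])
        out = interpolate_missing(seq, 0.3)
        assert np.allclose(out.data[:2, 1, 0], [1.0, 1.0])
        assert np.isclose(out.data[2, 1, 0], 0.3)   # repaired confidence

    def test_leading_and_trailing_gaps_copy_nearest_valid_frame(self):
        seq = self.make_seq([50.0, 7.0, 50.0], [0.1, 0.9, 0.1])
        out = interpolate_missing(seq, 0.3)
        assert np.allclose(out.data[0, :, 0], [7.0, 7.0, 7.0])

    def test_joint_never_valid_left_unchanged_with_warning(self):
        seq = self.make_seq([5.0, 6.0, 7.0], [0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="no frame reaches"):
            out = interpolate_missing(seq, 0.3)
        assert np.array_equal(out.data[:2, :, 0], seq.data[:2, :, 0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        data = np.stack([r.uniform(0, 100, (10, 17)), r.uniform(0, 100, (10, 17)),
                         r.uniform(0, 1, (10, 17))]).astype(np.float32)
        seq = SkeletonSequence(data)
        once = interpolate_missing(seq, 0.3)
        twice = interpolate_missing(once, 0.3)
        assert np.array_equal(once.data, twice.data)


class TestJointsToBones:
    def test_child_minus_parent_by_hand(self):
        graph = build_graph("our")
        data = np.zeros((3, 1, 17), dtype=np.float32)
        data[2] = 1.0
        nose, neck = 0, graph.center_index
        data[0, 0, nose], data[1, 0, nose] = 3.0, 4.0
        data[0, 0, neck], data[1, 0, neck] = 1.0, 1.0
        bones = joints_to_bones(SkeletonSequence(data), graph)
        assert np.allclose(bones.data[:2, 0, nose], [2.0, 3.0])

    def test_root_bone_is_zero_every_frame(self, rng):
        graph = build_graph("our")
        data = np.stack([rng.uniform(0, 100, (5, 17)), rng.uniform(0, 100, (5, 17)),
                         rng.uniform(0, 1, (5, 17))]).astype(np.float32)
        bones = joints_to_bones(SkeletonSequence(data), graph)
        assert np.allclose(bones.data[:2, :, graph.center_index], 0.0)

    def test_coincident_points_give_all_zero_bones(self):
        graph = build_graph("new")
        data = np.full((3, 4, 17), 5.0, dtype=np.float32)
        data[2] = 0.8
        bones = joints_to_bones(SkeletonSequence(data), graph)
        assert np.allclose(bones.data[:2], 0.0)

    def test_confidence_is_minimum_of_child_and_parent(self):
        graph = build_graph("new")
        data = np.ones((3, 1, 17), dtype=np.float32)
        data[2, 0, 0] = 0.9            # nose
        data[2, 0, graph.parents[0]] = 0.2
        bones = joints_to_bones(SkeletonSequence(data), graph)
        assert np.isclose(bones.data[2, 0, 0], 0.2)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=20, deadline=None)
    def test_translation_invariance(self, dx, dy):
        graph = build_graph("our")
        r = np.random.default_rng(7)
        data = np.stack([r.uniform(100, 500, (3, 17)), r.uniform(100, 500, (3, 17)),
                         r.uniform(0.5, 1, (3, 17))]).astype(np.float32)
        shifted = data.copy()
        shifted[0] += np.float32(dx)
        shifted[1] += np.float32(dy)
        a = joints_to_bones(SkeletonSequence(data), graph)
        b = joints_to_bones(SkeletonSequence(shifted), graph)
        assert np.allclose(a.data[:2], b.data[:2], atol=1e-3)

    def test_pipeline_preserves_shape_end_to_end(self, tmp_path, rng):
        records = make_alphapose_records(60, rng=rng)
        path = tmp_path / "p.json"
        path.write_text(json.dumps(records))
        body, _ = assemble_sequence(read_alphapose_json(path), 60)
        repaired = interpolate_missing(body, 0.3)
        bones = joints_to_bones(repaired, build_graph("our"))
        assert bones.data.shape == (3, 60, 17)


class TestArchives:
    def test_sample_roundtrip(self, tmp_path, rng):
        body = SkeletonSequence(
            np.clip(rng.uniform(0, 1, (3, 60, 17)), 0, 1).astype(np.float32))
        face = FaceSequence(
            np.clip(rng.uniform(0, 1, (60, 68, 3)), 0, 1).astype(np.float32))
        save_sample(tmp_path / "s.npz", body, face, label=3)
        b2, f2, label = load_sample(tmp_path / "s.npz")
        assert label == 3
        assert np.array_equal(b2.data, body.data)
        assert np.array_equal(f2.data, face.data)
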