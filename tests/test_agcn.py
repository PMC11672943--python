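"""Skeleton-branch model components against brute-force oracles, plus the
architecture's shape and parameter-budget contracts."""

import numpy as np
import pytest

from motionfuse import nn
from motionfuse.agcn import (AGCNBlock, CBAM, ChannelAttention, GraphConvolution,
                             MotionAttention, MultiScaleTap, SkeletonBackbone,
                             UnitTCN, build_skeleton_model, count_flops,
                             count_params)
from motionfuse.autodiff import Tensor
from motionfuse.graph import build_graph, partition_adjacency


def random_stack(rng, V, K=3):
    """A random nonnegative normalized adjacency stack for oracle tests."""
    A = rng.uniform(0, 1, (K, V, V)).astype(np.float32)
    return A / A.sum(axis=1, keepdims=True)


def dense_graph_conv_oracle(gcn: GraphConvolution, x: np.ndarray) -> np.ndarray:
    """Re-derive the graph convolution with plain dense NumPy products."""
    N, C, T, V = x.shape
    ce = gcn.embed_channels
    y = np.zeros((N, gcn.conv_d[0].weight.shape[0], T, V))
    for k in range(gcn.num_subsets):
        M = gcn.A[k] + gcn.B.data[k]
        if gcn.attention:
            wa, ba = gcn.conv_a[k].weight.data[:, :, 0, 0], gcn.conv_a[k].bias.data
            wb, bb = gcn.conv_b[k].weight.data[:, :, 0, 0], gcn.conv_b[k].bias.data
            ea = np.einsum("ec,nctv->netv", wa, x) + ba[None, :, None, None]
            eb = np.einsum("ec,nctv->netv", wb, x) + bb[None, :, None, None]
            sim = np.einsum("netv,netw->nvw", ea, eb) / (ce * T)
            sim -= sim.max(axis=-1, keepdims=True)
            Ck = np.exp(sim) / np.exp(sim).sum(axis=-1, keepdims=True)
            M = M + Ck
        xa = (np.einsum("nctv,nvw->nctw", x, M) if M.ndim == 3
              else np.einsum("nctv,vw->nctw", x, M))
        wd, bd = gcn.conv_d[k].weight.data[:, :, 0, 0], gcn.conv_d[k].bias.data
        y += np.einsum("oc,nctv->notv", wd, xa) + bd[None, :, None, None]
    # eval-mode batch norm with fresh running stats is a near-identity map
    y = y / np.sqrt(1.0 + 1e-5)
    if isinstance(gcn.down, nn.Identity):
        y += x
    return np.maximum(y, 0.0)


class TestGraphConvolution:
    @pytest.mark.parametrize("V", [3, 4, 5])
    def test_matches_dense_matrix_oracle(self, rng, V):
        gcn = GraphConvolution(4, 4, random_stack(rng, V), rng=rng).eval()
        x = rng.standard_normal((2, 4, 6, V)).astype(np.float32)
        out = gcn(Tensor(x)).data
        assert np.allclose(out, dense_graph_conv_oracle(gcn, x), rtol=1e-5,
                           atol=1e-5)

    def test_identity_configuration_reproduces_input(self, rng):
        """A=I, B=0, attention off, W=I: the layer passes input through."""
        V = 5
        adj = np.eye(V, dtype=np.float32)[None]
        gcn = GraphConvolution(3, 3, adj, attention=False, rng=rng).eval()
        gcn.B.data[:] = 0.0
        gcn.conv_d[0].weight.data[:] = np.eye(3).reshape(3, 3, 1, 1)
        gcn.conv_d[0].bias.data[:] = 0.0
        x = rng.uniform(0.1, 1.0, (2, 3, 4, V)).astype(np.float32)
        out = gcn(Tensor(x)).data
        # residual adds x once more; eval-mode batch norm is ~identity
        expected = x / np.sqrt(1.0 + 1e-5) + x
        assert np.allclose(out, expected, rtol=1e-5, atol=1e-6)

    def test_attention_rows_form_probability_distributions(self, rng):
        gcn = GraphConvolution(3, 8, random_stack(rng, 17), rng=rng)
        x = Tensor(rng.standard_normal((2, 3, 10, 17)).astype(np.float32))
        for k in range(3):
            Ck = gcn.attention_adjacency(x, k).data
            assert np.allclose(Ck.sum(axis=-1), 1.0, atol=1e-6)
            assert (Ck >= 0).all()

    def test_vertex_mismatch_raises(self, rng):
        gcn = GraphConvolution(3, 4, random_stack(rng, 5), rng=rng)
        with pytest.raises(ValueError, match="vertex count"):
            gcn(Tensor(np.zeros((1, 3, 4, 7), dtype=np.float32)))


class TestTemporalConvAndAttention:
    def test_tap_output_nonnegative_and_zero_maps_to_zero(self, rng):
        tap = MultiScaleTap(4, 8, pool=2, rng=rng).eval()
        tap.conv.bias.data[:] = 0.0
        x = rng.standard_normal((2, 4, 8, 5)).astype(np.float32)
        out = tap(Tensor(x)).data
        assert out.min() >= 0.0                                # ReLU bound
        zero = tap(Tensor(np.zeros((2, 4, 8, 5), dtype=np.float32))).data
        assert np.allclose(zero, 0.0)

    def test_temporal_conv_matches_sliding_window_sum(self, rng):
        tcn = UnitTCN(1, 1, kernel_size=3, rng=rng).eval()
        tcn.conv.weight.data[:] = 1.0 / 3.0                    # averaging kernel
        tcn.conv.bias.data[:] = 0.0
        x = rng.standard_normal((1, 1, 12, 1)).astype(np.float32)
        out = tcn(Tensor(x)).data[0, 0, :, 0]
        padded = np.pad(x[0, 0, :, 0], 1)
        brute = np.array([padded[t:t + 3].mean() for t in range(12)])
        assert np.allclose(out, brute / np.sqrt(1 + 1e-5), rtol=1e-5, atol=1e-6)

    def test_cbam_maps_bounded_and_attenuating(self, rng):
        cbam = CBAM(8, reduction=4, rng=rng)
        x = rng.standard_normal((2, 8, 6, 5)).astype(np.float32)
        mc = cbam.channel(Tensor(x)).data
        ms = cbam.temporal(Tensor(x)).data
        assert (0 < mc).all() and (mc < 1).all()
        assert (0 < ms).all() and (ms < 1).all()
        out = cbam(Tensor(x)).data
        assert (np.abs(out) <= np.abs(x) + 1e-7).all()

    def test_channel_attention_matches_closed_form(self, rng):
        """Two-channel toy input vs a hand computation of the gate."""
        ca = ChannelAttention(2, reduction=1, rng=rng)
        x = rng.standard_normal((1, 2, 3, 4)).astype(np.float32)
        w1, b1 = ca.fc1.weight.data, ca.fc1.bias.data
        w2, b2 = ca.fc2.weight.data, ca.fc2.bias.data
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        mlp = lambda v: np.maximum(v @ w1 + b1, 0) @ w2 + b2
        gate = 1.0 / (1.0 + np.exp(-(mlp(avg) + mlp(mx))))
        assert np.allclose(ca(Tensor(x)).data[:, :, 0, 0], gate, rtol=1e-5)

    def test_tap_shapes_and_divisibility_contract(self, rng):
        tap = MultiScaleTap(16, 32, pool=4, rng=rng).eval()
        out = tap(Tensor(np.zeros((1, 16, 60, 17), dtype=np.float32)))
        assert out.shape == (1, 32, 15, 17)
        with pytest.raises(ValueError, match="pool"):
            tap(Tensor(np.zeros((1, 16, 58, 17), dtype=np.float32)))


class TestMotionAttention:
    def test_shape_preserved_and_scores_bounded(self, rng):
        mae = MotionAttention(rng=rng)
        x = rng.standard_normal((2, 8, 20, 17)).astype(np.float32)
        out = mae(Tensor(x))
        assert out.shape == x.shape
        scores = mae.frame_scores(Tensor(x)).data
        assert scores.shape == (2, 1, 20, 1)
        assert (0 < scores).all() and (scores < 1).all()

    def test_time_constant_input_gets_uniform_scores(self, rng):
        mae = MotionAttention(rng=rng)
        frame = rng.standard_normal((1, 8, 1, 17)).astype(np.float32)
        x = np.repeat(frame, 24, axis=2)
        scores = mae.frame_scores(Tensor(x)).data[0, 0, :, 0]
        # interior frames see identical statistics (edges differ via padding)
        assert np.allclose(scores[4:-4], scores[12], atol=1e-6)
        out = mae(Tensor(x)).data
        assert np.allclose(out[0, :, 12], x[0, :, 12] * scores[12], rtol=1e-5)

    def test_high_magnitude_frame_scores_highest_under_averaging_conv(self, rng):
        mae = MotionAttention(rng=rng)
        # positive center-peaked kernel so the hot frame wins outright
        profile = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1], dtype=np.float32) / 25.0
        mae.conv.weight.data[:] = profile.reshape(1, 1, 9, 1)
        mae.conv.bias.data[:] = 0.0
        x = np.full((1, 4, 30, 17), 0.01, dtype=np.float32)
        x[0, :, 15] = 5.0
        scores = mae.frame_scores(Tensor(x)).data[0, 0, :, 0]
        assert scores.argmax() == 15
        assert scores[15] > scores[0]


class TestBackbone:
    def test_stage_summands_align_for_sixty_frame_input(self):
        """The two tap outputs and the final stage output all reach
        (256, 15, 17) for a (3, 60, 17) input, so their sum is defined."""
        model = build_skeleton_model(seed=0).eval()
        x = Tensor(np.random.default_rng(1).standard_normal(
            (1, 3, 60, 17)).astype(np.float32))
        out4, out7, out10 = model._stage_outputs(x)
        assert out4.shape == (1, 64, 60, 17)
        assert out7.shape == (1, 128, 30, 17)
        assert out10.shape == (1, 256, 15, 17)
        t1, t2 = model.tap1(out4), model.tap2(out7)
        assert t1.shape == t2.shape == out10.shape
        logits = model(x)
        assert logits.shape == (1, 6)
        assert np.isfinite(logits.data).all()
        assert np.isclose(logits.softmax(axis=1).data.sum(), 1.0, atol=1e-6)

    def test_disabling_frame_attention_reproduces_plain_backbone(self, rng):
        model = build_skeleton_model(seed=3, base_channels=8)
        x = Tensor(rng.standard_normal((2, 3, 60, 17)).astype(np.float32))
        model.eval()
        with_mae = model(x).data
        model.use_mae = False
        without = model(x).data
        model.use_mae = True
        scores_one = model.mae.frame_scores
        model.mae.frame_scores = lambda t: Tensor(
            np.ones((t.shape[0], 1, t.shape[2], 1), dtype=np.float32))
        forced = model(x).data
        model.mae.frame_scores = scores_one
        assert np.array_equal(without, forced)     # scores forced to 1 == off
        assert not np.array_equal(with_mae, without)

    def test_one_sgd_step_decreases_loss(self, rng):
        """Differentiability sanity through the taps and frame attention."""
        model = build_skeleton_model(seed=0, base_channels=8)
        x = Tensor(rng.standard_normal((2, 3, 60, 17)).astype(np.float32) * 0.1)
        y = np.array([1, 4])
        opt = nn.SGD(model.parameters(), lr=0.05, weight_decay=0.0)
        model.train()
        first = nn.cross_entropy(model(x), y)
        opt.zero_grad()
        first.backward()
        opt.step()
        second = nn.cross_entropy(model(x), y)
        assert float(second.data) < float(first.data)

    def test_invalid_mae_stage_rejected(self):
        with pytest.raises(ValueError, match="mae_stage"):
            build_skeleton_model(mae_stage=5)

    def test_wrong_input_shape_raises(self):
        model = build_skeleton_model(seed=0, base_channels=8)
        with pytest.raises(ValueError, match="expected input"):
            model(Tensor(np.zeros((1, 3, 60, 11), dtype=np.float32)))


class TestComplexityAccounting:
    def test_reference_parameter_budgets(self):
        plain = build_skeleton_model(use_msst=False, use_mae=False, seed=0)
        full = build_skeleton_model(seed=0)
        assert round(count_params(plain) / 1e6, 2) == 3.44
        assert round(count_params(full) / 1e6, 2) == 3.91

    def test_budget_delta_dominated_by_the_two_tap_convs(self):
        plain = build_skeleton_model(use_msst=False, use_mae=False, seed=0)
        full = build_skeleton_model(seed=0)
        delta = count_params(full) - count_params(plain)
        tap_convs = (full.tap1.conv.weight.data.size + full.tap1.conv.bias.data.size
                     + full.tap2.conv.weight.data.size + full.tap2.conv.bias.data.size)
        assert 64 * 256 * 9 + 256 + 128 * 256 * 9 + 256 == tap_convs
        assert tap_convs / delta > 0.9
        assert 0.4e6 < delta < 0.55e6              # ~0.47 M

    def test_single_linear_layer_count_closed_form(self, rng):
        assert count_params(nn.Linear(256, 6, rng=rng)) == 256 * 6 + 6

    def test_two_layer_toy_count_matches_enumeration(self, rng):
        toy = nn.Sequential(nn.Conv2d(2, 3, (3, 1), rng=rng), nn.Linear(4, 5, rng=rng))
        by_hand = (3 * 2 * 3 * 1 + 3) + (4 * 5 + 5)
        assert count_params(toy) == by_hand
        assert count_params(toy) == sum(p.data.size for p in toy.parameters())

    def test_pointwise_conv_flops_closed_form(self, rng):
        conv = nn.Conv2d(2, 3, 1, rng=rng)
        flops = count_flops(conv, input_shape=(2, 2, 2))   # 4 positions
        assert flops == 2 * 2 * 3 * 4

    def test_two_layer_flops_match_per_layer_hand_count(self, rng):
        model = nn.Sequential(nn.Conv2d(2, 4, (3, 1), padding=(1, 0), rng=rng),
                              nn.Conv2d(4, 3, 1, rng=rng))
        flops = count_flops(model, input_shape=(2, 5, 2))
        hand = 2 * (2 * 4 * 3) * (5 * 2) + 2 * (4 * 3) * (5 * 2)
        assert flops == hand

    def test_empty_model_counts_zero(self):
        assert count_flops(nn.Sequential(), input_shape=(1, 2, 2)) == 0.0
        assert count_params(nn.Sequential()) == 0
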