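"""Stage-1 gait network: graph convolution, blocks, attention, full model."""

import numpy as np
import pytest

from adcascade import nn
from adcascade.astgcn import (
    AstGcn,
    AstGcnConfig,
    GraphSpatialConv,
    HourglassAttention,
    STGCNBlock,
    spatial_graph_conv,
)
from adcascade.graph import build_graph, partition_adjacency

from conftest import random_tree


def graph_conv_oracle(features, subsets, edge_masks, weights, bias=None):
    """Nested-loop reference: per clip, per subset, per node, per channel."""
    B, C_in, T, V = features.shape
    K, C_out = weights.shape[0], weights.shape[1]
    out = np.zeros((B, C_out, T, V))
    for b in range(B):
        for k in range(K):
            A = subsets[k] * (edge_masks[k] if edge_masks is not None else 1.0)
            for t in range(T):
                for v in range(V):
                    acc = np.zeros(C_out)
                    for u in range(V):
                        if A[v, u] != 0.0:
                            acc += A[v, u] * (weights[k] @ features[b, :, t, u])
                    out[b, :, t, v] += acc
    if bias is not None:
        out += bias[None, :, None, None]
    return out


class TestGraphSpatialConv:
    def test_single_node_self_loop_identity_weights(self):
        adj = partition_adjacency(build_graph([], 1))
        x = np.random.default_rng(0).standard_normal((1, 2, 4, 1)).astype(np.float32)
        w = np.zeros((3, 2, 2), dtype=np.float32)
        w[0] = np.eye(2)  # root subset carries the self-loop
        out = spatial_graph_conv(x, adj.subsets, None, w)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_all_ones_mask_reduces_to_unmasked_form(self, rng, toy_adjacency):
        x = rng.standard_normal((2, 3, 5, 5)).astype(np.float32)
        w = rng.standard_normal((3, 4, 3)).astype(np.float32)
        masked = spatial_graph_conv(x, toy_adjacency.subsets, np.ones((3, 5, 5)), w)
        unmasked = spatial_graph_conv(x, toy_adjacency.subsets, None, w)
        np.testing.assert_allclose(masked, unmasked, atol=1e-6)

    def test_matches_nested_loop_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(2, 8))
            adj = partition_adjacency(build_graph(random_tree(rng, n), n))
            layer = GraphSpatialConv(3, 4, adj.subsets, rng)
            layer.M.value[...] = rng.uniform(0.5, 1.5, layer.M.value.shape)
            x = rng.standard_normal((2, 3, 4, n)).astype(np.float32)
            got = layer.forward(x)
            want = graph_conv_oracle(
                x.astype(np.float64), adj.subsets,
                layer.M.value.astype(np.float64),
                layer.W.value.astype(np.float64),
                layer.b.value.astype(np.float64),
            )
            np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)

    def test_layer_with_unit_masks_equals_functional_form(self, rng, toy_adjacency):
        layer = GraphSpatialConv(3, 4, toy_adjacency.subsets, rng)
        x = rng.standard_normal((2, 3, 6, 5)).astype(np.float32)
        got = layer.forward(x)
        want = spatial_graph_conv(
            x, toy_adjacency.subsets.astype(np.float32), None,
            layer.W.value, layer.b.value,
        )
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_rejects_wrong_joint_count(self, rng, toy_adjacency):
        layer = GraphSpatialConv(3, 4, toy_adjacency.subsets, rng)
        with pytest.raises(ValueError, match="joints"):
            layer.forward(rng.standard_normal((1, 3, 4, 7)).astype(np.float32))


class TestSTGCNBlock:
    @pytest.mark.parametrize("stride,t_out", [(1, 60), (2, 30)])
    def test_temporal_stride_shapes(self, rng, toy_adjacency, stride, t_out):
        block = STGCNBlock(3, 8, toy_adjacency.subsets, 9, stride, 0.0, rng)
        out = block.forward(rng.standard_normal((2, 3, 60, 5)).astype(np.float32))
        assert out.shape == (2, 8, t_out, 5)

    def test_zero_temporal_kernel_without_residual_gives_zeros(self, rng, toy_adjacency):
        block = STGCNBlock(3, 4, toy_adjacency.subsets, 5, 1, 0.0, rng, residual=False)
        block.tcn.W.value[...] = 0.0
        block.tcn.b.value[...] = 0.0
        out = block.forward(rng.standard_normal((2, 3, 12, 5)).astype(np.float32))
        np.testing.assert_array_equal(out, 0.0)


class TestHourglassAttention:
    def test_shape_preserved(self, rng):
        att = HourglassAttention(4, rng)
        x = rng.standard_normal((2, 4, 60, 5)).astype(np.float32)
        assert att.forward(x).shape == x.shape

    def test_output_bounded_by_one_to_two_times_input(self, rng):
        att = HourglassAttention(4, rng)
        x = np.abs(rng.standard_normal((2, 4, 32, 5))).astype(np.float32)
        y = att.forward(x)
        assert (y >= x - 1e-6).all() and (y <= 2 * x + 1e-6).all()

    def test_zeroed_mask_branch_gives_1p5x(self, rng):
        att = HourglassAttention(4, rng)
        att.head.W.value[...] = 0.0
        att.head.b.value[...] = 0.0
        x = rng.standard_normal((1, 4, 16, 3)).astype(np.float32)
        np.testing.assert_allclose(att.forward(x), 1.5 * x, atol=1e-6)

    def test_non_divisible_length_is_handled(self, rng):
        att = HourglassAttention(2, rng)
        x = rng.standard_normal((1, 2, 37, 3)).astype(np.float32)
        assert att.forward(x).shape == x.shape


class TestAstGcnModel:
    @pytest.fixture
    def model(self, toy_adjacency):
        cfg = AstGcnConfig(
            channels=(8, 8, 16), strides=(1, 2, 2), temporal_kernel=5,
            attention="after-2", dropout=0.0, dropout_from_block=99,
        )
        return AstGcn(cfg, toy_adjacency, seed=0)

    def test_zeroed_head_gives_uniform_scores(self, model, rng):
        model.fc.W.value[...] = 0.0
        model.fc.b.value[...] = 0.0
        x = rng.standard_normal((3, 3, 16, 5)).astype(np.float32)
        np.testing.assert_allclose(model.predict_proba(x), 0.5, atol=1e-7)

    def test_batch_of_clips_yields_batch_of_scores(self, model, rng):
        x = rng.standard_normal((7, 3, 16, 5)).astype(np.float32)
        assert model.predict_proba(x).shape == (7, 2)

    def test_permuting_batch_permutes_outputs(self, model, rng):
        x = rng.standard_normal((6, 3, 16, 5)).astype(np.float32)
        perm = rng.permutation(6)
        base = model.forward(x)
        np.testing.assert_allclose(model.forward(x[perm]), base[perm], atol=1e-5)

    def test_eval_forward_is_deterministic(self, model, rng):
        x = rng.standard_normal((4, 3, 16, 5)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_wrong_joint_count_rejected(self, model, rng):
        with pytest.raises(ValueError, match="graph"):
            model.forward(rng.standard_normal((1, 3, 16, 9)).astype(np.float32))

    def test_no_attention_means_no_gate_parameters(self, toy_adjacency):
        cfg = AstGcnConfig(channels=(8, 8), strides=(1, 1), attention="none")
        model = AstGcn(cfg, toy_adjacency, seed=0)
        assert model.attention_modules == []
        assert not any("att" in p.name for p in model.params())

    def test_attention_placement_adds_exactly_one_module(self, model):
        assert len(model.attention_modules) == 1

    def test_invalid_attention_placement_rejected(self):
        with pytest.raises(ValueError, match="placement"):
            AstGcnConfig(channels=(8, 8), strides=(1, 1), attention="after-9")

    def test_parameter_count_mode_invariant(self, model, rng):
        count = model.parameter_count()
        x = rng.standard_normal((2, 3, 16, 5)).astype(np.float32)
        model.forward(x, train=True)
        assert model.parameter_count() == count
        assert count == nn.parameter_count(model.params())

    def test_save_load_roundtrip(self, model, rng, tmp_path):
        x = rng.standard_normal((3, 3, 16, 5)).astype(np.float32)
        model.forward(x, train=True)  # populate running statistics
        before = model.predict_proba(x)
        path = tmp_path / "model.npz"
        model.save(path)
        restored = AstGcn.load(path)
        np.testing.assert_allclose(restored.predict_proba(x), before, atol=1e-7)
        assert restored.parameter_count() == model.parameter_count()

    def test_default_config_has_ten_blocks_with_late_attention(self):
        cfg = AstGcnConfig()
        assert len(cfg.channels) == 10
        assert cfg.attention_blocks() == (9,)
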