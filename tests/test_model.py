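"""Attention arithmetic against brute-force oracles; architecture contracts."""

import numpy as np
import pytest

from isletseg.autograd import Tensor
from isletseg.model import (AANet, AANetSpec, AffinityAttention, Encoder,
                            ResNetBlock, SFBlock, affinity, count_parameters,
                            normalize_affinity, weighted_feature)


# ---------------------------------------------------------------------------
# brute-force per-pixel oracles
# ---------------------------------------------------------------------------

def affinity_loop(q, k):
    cp, n = q.shape
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            w[i, j] = sum(q[c, i] * k[c, j] for c in range(cp))
    return w


def softmax_rows_loop(w):
    n = w.shape[0]
    a = np.zeros_like(w, dtype=float)
    for i in range(n):
        e = np.exp(w[i] - w[i].max())
        a[i] = e / e.sum()
    return a


def weighted_feature_loop(a, v):
    cp, n = v.shape
    h = np.zeros((cp, n))
    for c in range(cp):
        for i in range(n):
            h[c, i] = sum(a[i, j] * v[c, j] for j in range(n))
    return h


class TestAffinity:
    def test_hand_case(self):
        q = np.array([[1.0, 2.0]])
        w = affinity(q, q)
        np.testing.assert_allclose(w, [[1.0, 2.0], [2.0, 4.0]])

    def test_zero_query_gives_zero_affinity(self, rng):
        q = np.zeros((3, 5))
        k = rng.random((3, 5))
        assert (affinity(q, k) == 0).all()

    def test_matches_loop_oracle(self, rng):
        q = rng.standard_normal((3, 7))
        k = rng.standard_normal((3, 7))
        np.testing.assert_allclose(affinity(q, k), affinity_loop(q, k),
                                   atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            affinity(np.zeros((2, 3)), np.zeros((2, 4)))


class TestNormalizeAffinity:
    def test_hand_case(self):
        a = normalize_affinity(np.array([[1.0, 2.0], [2.0, 4.0]]))
        np.testing.assert_allclose(
            a, [[0.26894142, 0.73105858], [0.11920292, 0.88079708]],
            atol=1e-7)

    def test_constant_row_is_uniform(self):
        a = normalize_affinity(np.full((4, 4), 3.7))
        np.testing.assert_allclose(a, 0.25)

    def test_row_shift_invariance(self, rng):
        w = rng.standard_normal((5, 5))
        w2 = w.copy()
        w2[2] += 123.0
        np.testing.assert_allclose(normalize_affinity(w)[2],
                                   normalize_affinity(w2)[2], atol=1e-12)

    def test_overflow_safe(self):
        a = normalize_affinity(np.array([[1e4, 1e4 + 1.0]]))
        assert np.isfinite(a).all()

    def test_rows_sum_to_one_many_trials(self):
        """Row-stochasticity over 1000 random affinity matrices."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(2, 16))
            a = normalize_affinity(rng.standard_normal((n, n)) * 10)
            np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)
            assert (a >= 0).all() and (a <= 1).all()


class TestWeightedFeature:
    def test_identity_attention_returns_values(self, rng):
        v = rng.random((3, 6))
        np.testing.assert_allclose(weighted_feature(np.eye(6), v), v)

    def test_uniform_attention_returns_column_mean(self, rng):
        v = rng.random((2, 8))
        h = weighted_feature(np.full((8, 8), 1 / 8), v)
        np.testing.assert_allclose(h, np.tile(v.mean(axis=1, keepdims=True),
                                              (1, 8)), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        a = normalize_affinity(rng.standard_normal((9, 9)))
        v = rng.standard_normal((4, 9))
        np.testing.assert_allclose(weighted_feature(a, v),
                                   weighted_feature_loop(a, v), atol=1e-12)

    def test_dimension_error(self):
        with pytest.raises(ValueError):
            weighted_feature(np.eye(4), np.zeros((2, 5)))

    def test_random_instances_all_three_ops(self, rng):
        """affinity -> softmax -> aggregation vs. loops, C'<=4, N<=64."""
        for _ in range(10):
            cp = int(rng.integers(1, 5))
            n = int(rng.integers(2, 65))
            q, k = rng.standard_normal((2, cp, n))
            v = rng.standard_normal((cp, n))
            w = affinity(q, k)
            np.testing.assert_allclose(w, affinity_loop(q, k), atol=1e-6)
            a = normalize_affinity(w)
            np.testing.assert_allclose(a, softmax_rows_loop(w), atol=1e-6)
            np.testing.assert_allclose(weighted_feature(a, v),
                                       weighted_feature_loop(a, v), atol=1e-6)


class TestAttentionModule:
    def test_output_shape_preserved(self, rng):
        aam = AffinityAttention(8, c_prime_ratio=4,
                                rng=np.random.default_rng(0))
        x = Tensor(rng.random((2, 8, 4, 4)).astype(np.float32))
        assert aam(x).shape == x.shape

    def test_forward_matches_composition_of_sub_operations(self):
        """The module equals affinity -> softmax -> aggregation -> fuse
        computed step by step with the module's own weights."""
        rng0 = np.random.default_rng(3)
        aam = AffinityAttention(8, c_prime_ratio=1, rng=rng0).eval()
        x = np.random.default_rng(4).random((1, 8, 2, 4)).astype(np.float32)
        out = aam(Tensor(x)).data[0]

        def conv1x1(m, arr):
            return (np.einsum("oi,ihw->ohw", m.weight.data[:, :, 0, 0], arr)
                    + m.bias.data[:, None, None])

        h = x[0].astype(np.float64)
        q = conv1x1(aam.query, h).reshape(8, -1)
        k = conv1x1(aam.key, h).reshape(8, -1)
        v = conv1x1(aam.value, h).reshape(8, -1)
        a = normalize_affinity(affinity(q, k))
        hp = weighted_feature(a, v).reshape(8, 2, 4)
        expected = conv1x1(aam.fuse, np.concatenate([h, hp], axis=0))
        np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-5)

    def test_zero_projections_reduce_to_fused_input(self):
        """With Q=K=V weights zero, attention output is uniform-mean of a
        zero value map, so the module reduces to a 1x1 conv of [H, 0]."""
        aam = AffinityAttention(4, c_prime_ratio=2,
                                rng=np.random.default_rng(0)).eval()
        for m in (aam.query, aam.key, aam.value):
            m.weight.data[:] = 0
            m.bias.data[:] = 0
        x = np.random.default_rng(1).random((1, 4, 2, 2)).astype(np.float32)
        out = aam(Tensor(x)).data
        w = aam.fuse.weight.data[:, :, 0, 0]
        expected = (np.einsum("oi,bihw->bohw", w[:, :4], x)
                    + aam.fuse.bias.data[None, :, None, None])
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_capacity_error_on_large_maps(self):
        aam = AffinityAttention(4, 2, np.random.default_rng(0))
        x = Tensor(np.zeros((1, 4, 128, 128), dtype=np.float32))
        with pytest.raises(ValueError, match="bottleneck"):
            aam(x)


class TestBlocks:
    def test_sf_block_preserves_spatial_shape_and_nonnegative(self, rng):
        blk = SFBlock(3, 5, np.random.default_rng(0))
        y = blk(Tensor(rng.random((2, 3, 12, 12)).astype(np.float32)))
        assert y.shape == (2, 5, 12, 12)
        assert (y.data >= 0).all()

    def test_resnet_minus_sf_equals_shortcut(self, rng):
        """With shared weights, the residual block's output exceeds the
        shortcut-free block's output exactly by the shortcut path."""
        res = ResNetBlock(4, 4, np.random.default_rng(0))
        x = rng.random((1, 4, 8, 8)).astype(np.float32)
        res.eval()
        y_res = res(Tensor(x)).data
        y_sf = res.body.eval()(Tensor(x)).data
        np.testing.assert_allclose(y_res - y_sf, x, atol=1e-6)

    def test_resnet_zero_weights_passes_input_through(self):
        res = ResNetBlock(4, 4, np.random.default_rng(0)).eval()
        for conv in (res.body.conv1, res.body.conv2):
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        x = np.random.default_rng(2).random((1, 4, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(res(Tensor(x)).data, x, atol=1e-6)

    def test_shortcut_carries_gradient_with_zero_conv_weights(self):
        res = ResNetBlock(4, 4, np.random.default_rng(0))
        for conv in (res.body.conv1, res.body.conv2):
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        x = Tensor(np.random.default_rng(3).random((1, 4, 8, 8))
                   .astype(np.float32), requires_grad=True)
        res(x).sum().backward()
        assert x.grad is not None and np.abs(x.grad).max() > 0


class TestEncoder:
    @pytest.mark.parametrize("side,bottleneck", [(128, 8), (16, 1), (64, 4)])
    def test_bottleneck_is_input_over_16(self, side, bottleneck):
        enc = Encoder(AANetSpec(base_channels=4), np.random.default_rng(0))
        x = Tensor(np.zeros((1, 1, side, side), dtype=np.float32))
        y, skips = enc(x)
        assert y.shape[-2:] == (bottleneck, bottleneck)

    def test_stage_shapes_match_schedule(self):
        spec = AANetSpec(base_channels=4)
        enc = Encoder(spec, np.random.default_rng(0))
        y, skips = enc(Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        # pre-pool skip features: full, /2, /4, /8 resolution
        assert [s.shape for s in skips] == [
            (1, 4, 64, 64), (1, 8, 32, 32), (1, 16, 16, 16), (1, 32, 8, 8)]
        assert y.shape == (1, 32, 4, 4)

    def test_indivisible_shape_rejected(self):
        enc = Encoder(AANetSpec(base_channels=4), np.random.default_rng(0))
        with pytest.raises(ValueError, match="divisible by 16"):
            enc(Tensor(np.zeros((1, 1, 60, 60), dtype=np.float32)))


class TestAANet:
    def test_output_in_unit_interval_and_same_shape(self, rng):
        net = AANet(AANetSpec(base_channels=4), 0)
        p = net.predict_proba(rng.random((2, 32, 32)))
        assert p.shape == (2, 32, 32)
        assert (p >= 0).all() and (p <= 1).all()

    def test_inference_is_deterministic(self, rng):
        net = AANet(AANetSpec(base_channels=4), 0)
        x = rng.random((1, 32, 32))
        p1 = net.predict_proba(x)
        p2 = net.predict_proba(x)
        assert (p1 == p2).all()

    def test_identical_seeds_build_identical_networks(self, rng):
        a = AANet(AANetSpec(base_channels=4), 11)
        b = AANet(AANetSpec(base_channels=4), 11)
        x = rng.random((1, 32, 32))
        assert (a.predict_proba(x) == b.predict_proba(x)).all()

    def test_attention_ablation_reduces_parameter_count(self):
        full = AANet(AANetSpec(base_channels=4), 0)
        ablated = AANet(AANetSpec(base_channels=4, use_attention=False), 0)
        assert count_parameters(ablated) < count_parameters(full)

    def test_attention_changes_the_output(self, rng):
        full = AANet(AANetSpec(base_channels=4), 0)
        ablated = AANet(AANetSpec(base_channels=4, use_attention=False), 0)
        x = rng.random((1, 32, 32))
        assert not np.allclose(full.predict_proba(x),
                               ablated.predict_proba(x))
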