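"""Window attention, shifted windows, and the parallel attention block."""

import math
from dataclasses import replace

import numpy as np
import pytest

from binet.attention import (AttentionConfig, LayerNorm, Mlp, PABlock,
                             WindowAttention, layer_norm, swmsa_mask,
                             window_partition, window_reverse, wmsa, MASK_VALUE)
from binet.autodiff import Tensor


def make_attention(rng, dim, window_size, num_heads=1, shift=0):
    cfg = AttentionConfig(window_size=window_size, num_heads=num_heads,
                          head_dim=dim // num_heads, shift=shift)
    return WindowAttention(rng, cfg)


def set_identity(attn: WindowAttention):
    """Wq = Wk = Wv = proj = identity, zero bias table."""
    dim = attn.cfg.channels
    eye = np.eye(dim, dtype=np.float32)
    attn.wq.weight.data = eye.copy()
    attn.wk.weight.data = eye.copy()
    attn.wv.weight.data = eye.copy()
    attn.proj.weight.data = eye.copy()
    attn.proj.bias.data[:] = 0
    attn.bias_table.data[:] = 0


# ---------------------------------------------------------------------------
# layer norm and MLP
# ---------------------------------------------------------------------------

class TestLayerNorm:
    def test_constant_token_collapses_to_bias(self):
        x = Tensor(np.full((1, 1, 1, 8), 3.7, dtype=np.float32))
        out = layer_norm(x, np.ones(8), np.full(8, 0.25))
        np.testing.assert_allclose(out.data, 0.25, atol=1e-5)

    def test_two_value_token(self):
        out = layer_norm(Tensor(np.array([[1.0, 3.0]])), np.ones(2), np.zeros(2),
                         eps=1e-12)
        np.testing.assert_allclose(out.data, [[-1.0, 1.0]], atol=1e-5)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.standard_normal((7, 7, 8)).astype(np.float32)
        gain = rng.standard_normal(8).astype(np.float32)
        bias = rng.standard_normal(8).astype(np.float32)
        out = layer_norm(Tensor(x), gain, bias, eps=1e-5).data
        # independent two-pass mean/variance computation in float64
        x64 = x.astype(np.float64)
        mu = x64.mean(-1, keepdims=True)
        var = ((x64 - mu) ** 2).mean(-1, keepdims=True)
        expected = (x64 - mu) / np.sqrt(var + 1e-5) * gain + bias
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_rejects_non_finite_input(self):
        bad = np.ones((1, 2), dtype=np.float32)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="stage_x"):
            layer_norm(Tensor(bad), np.ones(2), np.zeros(2), stage="stage_x")

    def test_rejects_nonpositive_epsilon(self):
        with pytest.raises(ValueError):
            LayerNorm(4, eps=0.0)


class TestMlp:
    def test_zero_input_zero_biases(self, rng):
        mlp = Mlp(rng, 6)
        out = mlp(Tensor(np.zeros((2, 3, 6), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_identity_maps_propagate_gelu(self, rng):
        mlp = Mlp(rng, 1, expansion_ratio=1)
        mlp.fc1.weight.data = np.ones((1, 1), dtype=np.float32)
        mlp.fc2.weight.data = np.ones((1, 1), dtype=np.float32)
        out = mlp(Tensor(np.array([[1.0]], dtype=np.float32)))
        gelu1 = 0.5 * (1.0 + math.erf(1.0 / math.sqrt(2.0)))   # ≈ 0.8413
        np.testing.assert_allclose(out.data, [[gelu1]], atol=1e-6)

    def test_matches_explicit_matrix_oracle(self, rng):
        mlp = Mlp(rng, 5)
        for p in mlp.parameters():
            p.data = rng.standard_normal(p.data.shape).astype(np.float32) * 0.5
        x = rng.standard_normal((4, 5)).astype(np.float32)
        out = mlp(Tensor(x)).data
        h = x @ mlp.fc1.weight.data + mlp.fc1.bias.data
        h = h * 0.5 * (1.0 + np.vectorize(math.erf)(h / math.sqrt(2.0)))
        expected = h @ mlp.fc2.weight.data + mlp.fc2.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_hidden_width_is_expansion_times_channels(self, rng):
        mlp = Mlp(rng, 6, expansion_ratio=4)
        assert mlp.fc1.weight.shape == (6, 24)
        assert mlp.fc2.weight.shape == (24, 6)


# ---------------------------------------------------------------------------
# window partition
# ---------------------------------------------------------------------------

class TestWindowPartition:
    def test_single_window(self, rng):
        x = rng.standard_normal((1, 4, 4, 3)).astype(np.float32)
        w = window_partition(Tensor(x), 4)
        assert w.shape == (1, 16, 3)

    def test_round_trip(self, grid_8x8):
        w = window_partition(Tensor(grid_8x8), 4)
        assert w.shape == (4, 16, 6)
        back = window_reverse(w, 4, 8, 8)
        np.testing.assert_array_equal(back.data, grid_8x8)

    def test_stage3_geometry(self, rng):
        x = rng.standard_normal((1, 7, 7, 4)).astype(np.float32)
        w = window_partition(Tensor(x), 7)
        assert w.shape == (1, 49, 4)

    def test_rejects_bad_window_size(self, grid_8x8):
        with pytest.raises(ValueError):
            window_partition(Tensor(grid_8x8), 0)
        with pytest.raises(ValueError):
            window_partition(Tensor(grid_8x8), 3)


# ---------------------------------------------------------------------------
# window attention
# ---------------------------------------------------------------------------

def dense_attention_oracle(x, attn: WindowAttention):
    """Brute-force per-head softmax attention over a full token set, written
    with explicit loops and float64 arithmetic."""
    x = x.astype(np.float64)
    n, c = x.shape
    h, d = attn.cfg.num_heads, attn.cfg.head_dim
    q = x @ attn.wq.weight.data.astype(np.float64)
    k = x @ attn.wk.weight.data.astype(np.float64)
    v = x @ attn.wv.weight.data.astype(np.float64)
    bias = attn.bias_table.data[attn._bias_index].reshape(n, n, h)
    out = np.zeros((n, c))
    for head in range(h):
        sl = slice(head * d, (head + 1) * d)
        for i in range(n):
            logits = np.array([q[i, sl] @ k[j, sl] / math.sqrt(d) + bias[i, j, head]
                               for j in range(n)])
            e = np.exp(logits - logits.max())
            p = e / e.sum()
            out[i, sl] = sum(p[j] * v[j, sl] for j in range(n))
    return out @ attn.proj.weight.data.astype(np.float64) + attn.proj.bias.data


class TestWindowAttention:
    def test_single_token_identity(self, rng):
        attn = make_attention(rng, dim=4, window_size=1)
        set_identity(attn)
        x = rng.standard_normal((1, 1, 4)).astype(np.float32)
        out = attn(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        attn = make_attention(rng, dim=8, window_size=4, num_heads=2)
        x = rng.standard_normal((3, 16, 8)).astype(np.float32)
        _, weights = attn(Tensor(x), return_weights=True)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_two_token_hand_computation(self, rng):
        """softmax(QKᵀ/√2)V with integer weight matrices, evaluated by hand."""
        attn = make_attention(rng, dim=2, window_size=2)
        set_identity(attn)
        attn.wk.weight.data = np.array([[0, 1], [1, 0]], dtype=np.float32)
        attn.wv.weight.data = np.array([[1, 2], [3, 4]], dtype=np.float32)
        x = np.eye(2, dtype=np.float32).reshape(1, 2, 2)
        out = attn(Tensor(x)).data[0]
        # Q = I rows, K rows swapped, V rows [1,2],[3,4]:
        # logits row 1 = [0, 1/√2]; p = [1, e^{1/√2}] normalized
        e = math.exp(1.0 / math.sqrt(2.0))
        p1 = np.array([1.0, e]) / (1.0 + e)
        p2 = p1[::-1]
        v = np.array([[1.0, 2.0], [3.0, 4.0]])
        expected = np.stack([p1 @ v, p2 @ v])
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_matches_dense_oracle(self, rng):
        attn = make_attention(rng, dim=6, window_size=3, num_heads=2)
        x = rng.standard_normal((9, 6)).astype(np.float32)
        out = attn(Tensor(x.reshape(1, 9, 6))).data[0]
        np.testing.assert_allclose(out, dense_attention_oracle(x, attn), atol=1e-6)

    def test_dimension_mismatch_raises(self, rng):
        attn = make_attention(rng, dim=6, window_size=3, num_heads=2)
        with pytest.raises(ValueError, match="head"):
            attn(Tensor(np.zeros((1, 9, 4), dtype=np.float32)))


class TestWmsa:
    def test_locality_under_perturbation(self, rng, grid_8x8):
        attn = make_attention(rng, dim=6, window_size=4, num_heads=2)
        base = attn.forward_grid(Tensor(grid_8x8)).data
        poked = grid_8x8.copy()
        poked[0, 1, 2, :] += 5.0          # token inside window (0, 0)
        diff = attn.forward_grid(Tensor(poked)).data - base
        changed = np.abs(diff[0]).sum(axis=-1) > 1e-6
        assert changed[:4, :4].any()
        assert not changed[:4, 4:].any()
        assert not changed[4:, :].any()

    def test_equals_independent_per_window_attention(self, rng, grid_8x8):
        attn = make_attention(rng, dim=6, window_size=4, num_heads=2)
        out = wmsa(Tensor(grid_8x8), attn).data[0]
        for wi in range(2):
            for wj in range(2):
                block = grid_8x8[0, 4 * wi:4 * wi + 4, 4 * wj:4 * wj + 4, :]
                expected = dense_attention_oracle(block.reshape(16, 6), attn)
                np.testing.assert_allclose(
                    out[4 * wi:4 * wi + 4, 4 * wj:4 * wj + 4].reshape(16, 6),
                    expected, atol=1e-5)

    def test_zero_grid_zero_bias_gives_constant_projection(self, rng):
        attn = make_attention(rng, dim=6, window_size=4)
        attn.bias_table.data[:] = 0
        out = attn.forward_grid(Tensor(np.zeros((1, 8, 8, 6), dtype=np.float32)))
        expected = np.broadcast_to(attn.proj.bias.data, out.shape)
        np.testing.assert_allclose(out.data, expected, atol=1e-7)

    def test_wmsa_rejects_shifted_config(self, rng):
        attn = make_attention(rng, dim=6, window_size=4, shift=2)
        with pytest.raises(ValueError):
            wmsa(Tensor(np.zeros((1, 8, 8, 6), dtype=np.float32)), attn)

    def test_padding_policy_preserves_shape(self, rng):
        attn = make_attention(rng, dim=6, window_size=4)
        x = rng.standard_normal((1, 6, 7, 6)).astype(np.float32)
        assert attn.forward_grid(Tensor(x)).shape == (1, 6, 7, 6)


class TestSwmsa:
    def test_shift_zero_reduces_to_wmsa(self, rng, grid_8x8):
        shifted = make_attention(rng, dim=6, window_size=4, num_heads=2, shift=2)
        plain = make_attention(rng, dim=6, window_size=4, num_heads=2, shift=0)
        plain.load_state_dict(shifted.state_dict())
        degenerate = make_attention(rng, dim=6, window_size=4, num_heads=2, shift=0)
        degenerate.load_state_dict(shifted.state_dict())
        a = degenerate.forward_grid(Tensor(grid_8x8)).data
        b = plain.forward_grid(Tensor(grid_8x8)).data
        np.testing.assert_allclose(a, b, atol=1e-6)
        # and the shifted version differs (windows exchange information)
        c = shifted.forward_grid(Tensor(grid_8x8)).data
        assert np.abs(c - b).max() > 1e-4

    def test_mask_forbids_exactly_wrapped_pairs(self):
        """Brute-force provenance enumeration on an 8×8 grid, S=4, shift=2."""
        H = W = 8
        S, s = 4, 2
        mask = swmsa_mask(H, W, S, s)
        assert mask.shape == (4, 16, 16)
        # original coordinate of each rolled position
        orig = np.empty((H, W, 2), dtype=int)
        for r in range(H):
            for c in range(W):
                orig[r, c] = ((r + s) % H, (c + s) % W)
        for wi in range(2):
            for wj in range(2):
                coords = [(4 * wi + a, 4 * wj + b) for a in range(4) for b in range(4)]
                widx = wi * 2 + wj
                for i, (ri, ci) in enumerate(coords):
                    for j, (rj, cj) in enumerate(coords):
                        # attention allowed iff rolling did not tear the pair
                        # apart: rolled offset equals original offset per axis
                        ok_r = (orig[ri, ci][0] - orig[rj, cj][0]) == (ri - rj)
                        ok_c = (orig[ri, ci][1] - orig[rj, cj][1]) == (ci - cj)
                        if ok_r and ok_c:
                            assert mask[widx, i, j] == 0.0, (widx, i, j)
                        else:
                            assert mask[widx, i, j] == MASK_VALUE, (widx, i, j)

    def test_masked_rows_still_normalize(self, rng, grid_8x8):
        attn = make_attention(rng, dim=6, window_size=4, num_heads=2, shift=2)
        x = Tensor(grid_8x8)
        from binet.autodiff import roll2d
        rolled = roll2d(x, -2, -2)
        mask = swmsa_mask(8, 8, 4, 2)
        _, weights = attn(window_partition(rolled, 4), mask=mask,
                          return_weights=True)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_shift_roundtrip_with_identity_attention(self, rng, grid_8x8):
        attn = make_attention(rng, dim=6, window_size=1, shift=0)
        set_identity(attn)
        out = attn.forward_grid(Tensor(grid_8x8)).data
        np.testing.assert_allclose(out, grid_8x8, atol=1e-6)


# ---------------------------------------------------------------------------
# parallel attention block
# ---------------------------------------------------------------------------

def tie_paths(block: PABlock):
    """Make the SWMSA path share weights with the WMSA path, with shift 0."""
    block.path_sw.load_state_dict(block.path_w.state_dict())
    block.path_sw.attn.cfg = replace(block.path_sw.attn.cfg, shift=0)


class TestPABlock:
    def test_tied_paths_double_single_path(self, rng, grid_8x8):
        block = PABlock(rng, dim=6, window_size=4, num_heads=2)
        tie_paths(block)
        x = Tensor(grid_8x8)
        out = block(x).data
        single = block.path_w(x).data
        np.testing.assert_allclose(out, 2.0 * single, atol=1e-6)

    def test_single_path_modes_match_their_path(self, rng, grid_8x8):
        full = PABlock(rng, dim=6, window_size=4, num_heads=2, mode="parallel")
        x = Tensor(grid_8x8)
        for mode, path in (("wmsa_only", full.path_w), ("swmsa_only", full.path_sw)):
            solo = PABlock(np.random.default_rng(0), dim=6, window_size=4,
                           num_heads=2, mode=mode)
            attr = "path_w" if mode == "wmsa_only" else "path_sw"
            getattr(solo, attr).load_state_dict(path.state_dict())
            np.testing.assert_allclose(solo(x).data, path(x).data, atol=1e-7)

    def test_matches_compositional_oracle(self, rng, grid_8x8):
        block = PABlock(rng, dim=6, window_size=4, num_heads=2)
        x = Tensor(grid_8x8)
        out = block(x).data

        def path(p, x):
            a = p.attn.forward_grid(p.norm1(x)) + x
            return (p.mlp(p.norm2(a)) + a).data
        expected = path(block.path_w, x) + path(block.path_sw, x)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_path_symmetry(self, rng, grid_8x8):
        block = PABlock(rng, dim=6, window_size=4, num_heads=2)
        x = Tensor(grid_8x8)
        a = (block.path_w(x) + block.path_sw(x)).data
        b = (block.path_sw(x) + block.path_w(x)).data
        np.testing.assert_allclose(a, b, atol=0)

    def test_preserves_shape(self, rng):
        for mode in ("parallel", "wmsa_only", "swmsa_only", "serial"):
            block = PABlock(rng, dim=6, window_size=4, num_heads=2, mode=mode)
            x = Tensor(np.random.default_rng(0)
                       .standard_normal((2, 8, 8, 6)).astype(np.float32))
            assert block(x).shape == (2, 8, 8, 6)

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ValueError, match="parallel"):
            PABlock(rng, dim=6, window_size=4, num_heads=2, mode="bogus")
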