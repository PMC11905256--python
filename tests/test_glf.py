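"""Global-local fusion: unfold/fold, transformer properties, fusion block."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssdaseg._tensor import Tensor
from ssdaseg.glf import (GLFBlock, GLFConfig, MultiHeadAttention, Transformer,
                         fold_patches, transformer_forward, unfold_patches)


class TestUnfoldFold:
    def test_documented_shape(self, rng):
        """(1, 4, 4, 4, 4) with 2x2x2 patches -> (1, P=8, N=8, d=4)."""
        x = rng.standard_normal((1, 4, 4, 4, 4))
        u = unfold_patches(Tensor(x))
        assert u.shape == (1, 8, 8, 4)

    @given(st.integers(1, 3), st.integers(1, 5),
           st.sampled_from([(2, 2, 2), (2, 4, 2), (4, 2, 2)]),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_is_bit_exact(self, b, c, dims_mult, seed):
        r = np.random.default_rng(seed)
        grid = tuple(2 * m for m in dims_mult)
        x = r.standard_normal((b, c) + grid).astype(np.float32)
        u = unfold_patches(Tensor(x))
        back = fold_patches(u, grid).data
        assert np.array_equal(back, x)

    def test_constant_input_gives_constant_slices(self):
        x = np.full((1, 3, 4, 4, 2), 2.5)
        u = unfold_patches(Tensor(x)).data
        assert np.all(u == 2.5)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError, match="axis H"):
            unfold_patches(Tensor(np.zeros((1, 2, 4, 5, 4))))

    def test_voxel_count_conserved(self, rng):
        x = rng.standard_normal((2, 3, 4, 6, 2))
        u = unfold_patches(Tensor(x))
        B, P, N, d = u.shape
        assert P * N == 4 * 6 * 2 and d == 3


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        mha = MultiHeadAttention(16, 8, rng=np.random.default_rng(0))
        z = Tensor(rng.standard_normal((2, 4, 6, 16)).astype(np.float32))
        _, attn = mha(z, return_attention=True)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_query_gives_uniform_attention_mean_of_values(self, rng):
        """softmax(0) attends uniformly: each output equals the value mean."""
        mha = MultiHeadAttention(8, 8, rng=np.random.default_rng(0))  # one head
        mha.q.weight.data = np.zeros_like(mha.q.weight.data)
        mha.q.bias.data = np.zeros_like(mha.q.bias.data)
        z = Tensor(rng.standard_normal((1, 2, 5, 8)).astype(np.float32))
        out, attn = mha(z, return_attention=True)
        np.testing.assert_allclose(attn.data, 1.0 / 5, atol=1e-6)
        v = mha.v(z).data
        want = v.mean(axis=2, keepdims=True)            # mean over N positions
        head_out = np.broadcast_to(want, v.shape)
        proj = head_out @ mha.proj.weight.data + mha.proj.bias.data
        np.testing.assert_allclose(out.data, proj, atol=1e-5)

    def test_permutation_equivariance_over_patch_positions(self, rng):
        """No positional embeddings: permuting the N tokens permutes outputs."""
        model = Transformer(16, depth=2, d_head=8, rng=np.random.default_rng(0))
        z = rng.standard_normal((1, 4, 7, 16)).astype(np.float32)
        perm = np.random.default_rng(9).permutation(7)
        out = model(Tensor(z)).data
        out_perm = model(Tensor(z[:, :, perm])).data
        np.testing.assert_allclose(out_perm, out[:, :, perm], atol=1e-5)

    def test_width_not_divisible_by_head_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(10, 8)
        with pytest.raises(ValueError, match="divisible"):
            GLFConfig(in_channels=20, d_head=8).validate()


class TestGLFBlock:
    def test_output_shape_preserved(self, rng):
        cfg = GLFConfig(in_channels=32, out_channels=32, d_head=8, depth=1)
        block = GLFBlock(cfg, rng=np.random.default_rng(0))
        x = rng.standard_normal((2, 32, 8, 8, 4)).astype(np.float32)
        assert block(Tensor(x)).shape == (2, 32, 8, 8, 4)

    def test_zeroed_projections_leave_only_fusion_bias(self, rng):
        cfg = GLFConfig(in_channels=8, out_channels=8, d_head=4, depth=1)
        block = GLFBlock(cfg, rng=np.random.default_rng(0))
        block.fuse_conv3.weight.data = np.zeros_like(block.fuse_conv3.weight.data)
        y1 = block(Tensor(rng.standard_normal((1, 8, 4, 4, 4)).astype(np.float32))).data
        y2 = block(Tensor(rng.standard_normal((1, 8, 4, 4, 4)).astype(np.float32))).data
        np.testing.assert_allclose(y1, y2, atol=1e-6)

    def test_depth_zero_reduces_to_convolutional_bottleneck(self, rng):
        """With L=0 the global path is fold(unfold(proj(x))) = proj(x):
        a pure convolutional block remains."""
        cfg = GLFConfig(in_channels=8, out_channels=8, d_head=4, depth=0)
        block = GLFBlock(cfg, rng=np.random.default_rng(0))
        x = rng.standard_normal((1, 8, 4, 4, 4)).astype(np.float32)
        y = block(Tensor(x)).data
        # manual: local path, global path = plain 1x1 projection
        from ssdaseg._tensor import cat
        x_t = Tensor(x)
        x_l = block.local_conv1(block.local_conv3(x_t).relu())
        x_g = block.global_proj(x_t)
        want = block.fuse_conv1(block.fuse_conv3(cat([x_l, x_g], axis=1)).relu()).data
        np.testing.assert_allclose(y, want, atol=1e-6)

    def test_global_path_reaches_distant_voxels(self, rng):
        """An impulse propagates through uniform attention to far-away voxels
        sharing the within-patch offset — a non-local receptive field no
        local convolution has."""
        d = 8
        mha = MultiHeadAttention(d, d, rng=np.random.default_rng(0))
        mha.q.weight.data = np.zeros_like(mha.q.weight.data)
        mha.q.bias.data = np.zeros_like(mha.q.bias.data)
        grid = (8, 8, 4)
        x = np.zeros((1, d) + grid, dtype=np.float32)
        x[0, :, 0, 0, 0] = 1.0                       # impulse at one corner
        u = unfold_patches(Tensor(x))
        out = fold_patches(mha(u), grid).data
        # the farthest voxel with the same within-patch offset (even indices)
        assert abs(out[0, :, 6, 6, 2]).max() > 1e-6

    def test_transformer_forward_validates_width(self):
        cfg = GLFConfig(in_channels=16, d_head=8)
        with pytest.raises(ValueError, match="width"):
            transformer_forward(np.zeros((1, 8, 4, 7)), cfg)
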