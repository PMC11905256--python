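"""Global-local fusion (GLF) bottleneck.

Convolutions at the UNet bottleneck still only see a local neighbourhood;
distinguishing, say, left kidney from spleen benefits from volume-wide
context.  The GLF block therefore runs two parallel paths over the
bottleneck feature map:

* a **local** path — a 3x3x3 then 1x1x1 convolution at width ``d = C_in/2``;
* a **global** path — project to width ``d``, unfold the volume into
  non-overlapping 2x2x2 patches, run a small pre-norm transformer over the
  patch positions (no positional embeddings), and fold back.

Attention operates across the N patch positions for each of the P = 8
within-patch offsets independently, on tensors shaped (B, P, N, d) — the
MobileViT-style factorization that keeps token counts small on 3D grids.
The two paths are concatenated (2d channels) and fused by shared
convolutions down to ``C_out``.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from ._tensor import Tensor, cat
from .nn import Conv3d, GELU, LayerNorm, Linear, Module, Sequential

__all__ = ["GLFConfig", "unfold_patches", "fold_patches", "MultiHeadAttention",
           "TransformerLayer", "Transformer", "GLFBlock", "transformer_forward",
           "glf_forward"]


@dataclass
class GLFConfig:
    in_channels: int = 128
    out_channels: int = 128
    patch: tuple[int, int, int] = (2, 2, 2)
    depth: int = 4               # transformer layers L
    d_head: int = 8              # per-head dimension
    mlp_ratio: int = 2

    @property
    def d(self) -> int:
        """Internal width of both paths: half the input channel count."""
        return self.in_channels // 2

    @property
    def n_heads(self) -> int:
        return self.d // self.d_head

    def validate(self) -> None:
        if self.in_channels % 2:
            raise ValueError("in_channels must be even (internal width d = C_in/2)")
        if self.d % self.d_head:
            raise ValueError(
                f"internal width d={self.d} must be divisible by d_head={self.d_head}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def _check_divisible(shape, patch):
    for name, n, p in zip("DHW", shape, patch):
        if n % p:
            raise ValueError(
                f"spatial axis {name} has size {n}, not divisible by patch size {p}")


def unfold_patches(x, patch: tuple[int, int, int] = (2, 2, 2)) -> Tensor:
    """Rearrange (B,C,D,H,W) into (B, P, N, C): P within-patch offsets, N patches.

    Purely a lossless reindexing — ``fold_patches`` inverts it bit-exactly.
    """
    x = Tensor._coerce(x)
    B, C, D, H, W = x.shape
    pd, ph, pw = patch
    _check_divisible((D, H, W), patch)
    nd, nh, nw = D // pd, H // ph, W // pw
    out = x.reshape(B, C, nd, pd, nh, ph, nw, pw)
    # (B, pd, ph, pw, nd, nh, nw, C) -> (B, P, N, C)
    out = out.transpose((0, 3, 5, 7, 2, 4, 6, 1))
    return out.reshape(B, pd * ph * pw, nd * nh * nw, C)


def fold_patches(x, grid: tuple[int, int, int],
                 patch: tuple[int, int, int] = (2, 2, 2)) -> Tensor:
    """Inverse of :func:`unfold_patches`; ``grid`` is the original (D,H,W)."""
    x = Tensor._coerce(x)
    B, P, N, C = x.shape
    D, H, W = grid
    pd, ph, pw = patch
    nd, nh, nw = D // pd, H // ph, W // pw
    if P != pd * ph * pw or N != nd * nh * nw:
        raise ValueError("patch tensor inconsistent with target grid")
    out = x.reshape(B, pd, ph, pw, nd, nh, nw, C)
    out = out.transpose((0, 7, 4, 1, 5, 2, 6, 3))
    return out.reshape(B, C, D, H, W)


class MultiHeadAttention(Module):
    """Scaled dot-product attention over the N (patch-position) axis."""

    def __init__(self, d: int, d_head: int, rng=None):
        super().__init__()
        if d % d_head:
            raise ValueError(f"model width {d} not divisible by head width {d_head}")
        self.d = d
        self.d_head = d_head
        self.n_heads = d // d_head
        self.q = Linear(d, d, rng=rng)
        self.k = Linear(d, d, rng=rng)
        self.v = Linear(d, d, rng=rng)
        self.proj = Linear(d, d, rng=rng)   # W_linear mixing the concatenated heads

    def _split(self, t: Tensor) -> Tensor:
        B, P, N, _ = t.shape
        return t.reshape(B, P, N, self.n_heads, self.d_head).transpose((0, 1, 3, 2, 4))

    def forward(self, z: Tensor, return_attention: bool = False):
        q, k, v = self._split(self.q(z)), self._split(self.k(z)), self._split(self.v(z))
        scores = (q @ k.transpose((0, 1, 2, 4, 3))) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)                 # rows over the key axis
        out = attn @ v                                 # (B, P, h, N, d_head)
        B, P, _, N, _ = out.shape
        out = out.transpose((0, 1, 3, 2, 4)).reshape(B, P, N, self.d)
        out = self.proj(out)
        if return_attention:
            return out, attn
        return out


class TransformerLayer(Module):
    """Pre-norm residual layer: z' = MHA(LN(z)) + z; z = MLP(LN(z')) + z'."""

    def __init__(self, d: int, d_head: int, mlp_ratio: int = 2, rng=None):
        super().__init__()
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadAttention(d, d_head, rng=rng)
        self.norm2 = LayerNorm(d)
        self.mlp = Sequential(Linear(d, mlp_ratio * d, rng=rng), GELU(),
                              Linear(mlp_ratio * d, d, rng=rng))

    def forward(self, z: Tensor) -> Tensor:
        z = self.attn(self.norm1(z)) + z
        return self.mlp(self.norm2(z)) + z


class Transformer(Module):
    def __init__(self, d: int, depth: int, d_head: int, mlp_ratio: int = 2, rng=None):
        super().__init__()
        self.depth = depth
        for i in range(depth):
            setattr(self, f"layer_{i}", TransformerLayer(d, d_head, mlp_ratio, rng=rng))

    def forward(self, z: Tensor) -> Tensor:
        for i in range(self.depth):
            z = getattr(self, f"layer_{i}")(z)
        return z


def transformer_forward(x_u, cfg: GLFConfig, model: Transformer | None = None) -> Tensor:
    """Run the GLF transformer on an unfolded (B,P,N,d) patch tensor."""
    cfg.validate()
    x_u = Tensor._coerce(x_u)
    if x_u.shape[-1] != cfg.d:
        raise ValueError(f"last axis {x_u.shape[-1]} != configured width d={cfg.d}")
    if model is None:
        model = Transformer(cfg.d, cfg.depth, cfg.d_head, cfg.mlp_ratio)
    return model(x_u)


class GLFBlock(Module):
    """Parallel local-conv and unfold->transformer->fold paths, fused by shared convs."""

    def __init__(self, cfg: GLFConfig, rng=None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        d = cfg.d
        self.local_conv3 = Conv3d(cfg.in_channels, d, 3, rng=rng)
        self.local_conv1 = Conv3d(d, d, 1, rng=rng)
        self.global_proj = Conv3d(cfg.in_channels, d, 1, rng=rng)
        self.transformer = Transformer(d, cfg.depth, cfg.d_head, cfg.mlp_ratio, rng=rng)
        self.fuse_conv3 = Conv3d(2 * d, cfg.out_channels, 3, rng=rng)
        self.fuse_conv1 = Conv3d(cfg.out_channels, cfg.out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor._coerce(x)
        grid = x.shape[2:]
        x_l = self.local_conv1(self.local_conv3(x).relu())
        x_u = unfold_patches(self.global_proj(x), self.cfg.patch)
        x_g = fold_patches(self.transformer(x_u), grid, self.cfg.patch)
        fused = cat([x_l, x_g], axis=1)
        return self.fuse_conv1(self.fuse_conv3(fused).relu())


def glf_forward(x, domain: str, cfg: GLFConfig, block: GLFBlock | None = None) -> Tensor:
    """Functional wrapper mirroring the block; the domain tag is accepted for
    signature parity with the domain-aware blocks but GLF itself is
    normalization-free and domain-agnostic."""
    if block is None:
        block = GLFBlock(cfg)
    return block(Tensor._coerce(x))
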