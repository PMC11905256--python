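"""Scale-aware block with domain-specific normalization (SAD).

Abdominal organs span an order of magnitude in size and the spread
differs between modalities, so a fixed receptive field under-serves
either the small kidneys or the large liver.  The SAD block runs two
parallel dilated 3x3x3 branches (dilation rates 1 and 3 by default) over
a shared Conv-D stem, recalibrates each branch with a squeeze-and-
excitation gate, concatenates, shuffles channels so the scales mix, and
finishes with a second Conv-D.  All normalization inside is DSBN, which
is what makes the block usable on mixed-domain training streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, cat
from .dsbn import ConvD
from .nn import Linear, Module

__all__ = ["ScaleAwareConfig", "SqueezeExcite", "channel_shuffle", "SADBlock",
           "se_recalibrate", "sad_forward"]


@dataclass
class ScaleAwareConfig:
    """Hyperparameters of one SAD block.

    ``dilation_rates`` must be distinct; channel counts must be divisible by
    ``shuffle_groups`` and by the number of branches (2).
    """
    in_channels: int = 16
    out_channels: int = 16
    kernel_size: int = 3
    dilation_rates: tuple[int, int] = (1, 3)
    se_reduction: int = 4
    shuffle_groups: int = 2

    def validate(self) -> None:
        d1, d2 = self.dilation_rates
        if d1 < 1 or d2 < 1 or d1 == d2:
            raise ValueError(f"dilation rates must be distinct and >= 1, got {self.dilation_rates}")
        if self.out_channels % 2:
            raise ValueError("out_channels must be even (two scale branches)")
        if self.out_channels % self.shuffle_groups:
            raise ValueError("out_channels must be divisible by shuffle_groups")


class SqueezeExcite(Module):
    """Channel recalibration: global average pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels: int, reduction: int = 4, rng=None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def weights(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3, 4))             # (B, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        w = self.weights(x)
        B, C = w.shape
        return x * w.reshape(B, C, 1, 1, 1)


def se_recalibrate(x, reduction: int = 4, *, block: SqueezeExcite | None = None) -> Tensor:
    """Apply squeeze-and-excitation gating to ``x`` (B,C,D,H,W)."""
    x = Tensor._coerce(x)
    if block is None:
        block = SqueezeExcite(x.shape[1], reduction)
    return block(x)


def channel_shuffle(x, groups: int) -> Tensor:
    """Permute channels by reshape (groups, C/groups) -> transpose -> flatten.

    With ``groups`` equal to the number of concatenated branches this
    interleaves the branches' channels, so the following convolution sees
    both scales in every group.
    """
    x = Tensor._coerce(x)
    B, C = x.shape[:2]
    if C % groups:
        raise ValueError(f"channel count {C} not divisible by groups {groups}")
    spatial = x.shape[2:]
    out = x.reshape(B, groups, C // groups, *spatial)
    axes = (0, 2, 1) + tuple(range(3, 3 + len(spatial)))
    return out.transpose(axes).reshape(B, C, *spatial)


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The channel permutation ``channel_shuffle`` realizes, as an index array."""
    return np.arange(channels).reshape(groups, channels // groups).T.reshape(-1)


class SADBlock(Module):
    """Conv-D stem -> two dilated+SE branches -> concat -> shuffle -> Conv-D."""

    domain_aware = True

    def __init__(self, cfg: ScaleAwareConfig, rng=None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c_out = cfg.out_channels
        half = c_out // 2
        self.stem = ConvD(cfg.in_channels, c_out, cfg.kernel_size, rng=rng)
        d1, d2 = cfg.dilation_rates
        # each branch emits half the channels so the concatenation restores c_out
        self.branch1 = ConvD(c_out, half, cfg.kernel_size, dilation=d1, rng=rng)
        self.branch2 = ConvD(c_out, half, cfg.kernel_size, dilation=d2, rng=rng)
        self.se1 = SqueezeExcite(half, cfg.se_reduction, rng=rng)
        self.se2 = SqueezeExcite(half, cfg.se_reduction, rng=rng)
        self.out = ConvD(c_out, c_out, cfg.kernel_size, rng=rng)

    def forward(self, x: Tensor, domain: str) -> Tensor:
        h = self.stem(x, domain)
        b1 = self.se1(self.branch1(h, domain))
        b2 = self.se2(self.branch2(h, domain))
        mixed = channel_shuffle(cat([b1, b2], axis=1), self.cfg.shuffle_groups)
        return self.out(mixed, domain)


def sad_forward(x, domain: str, cfg: ScaleAwareConfig, block: SADBlock | None = None) -> Tensor:
    """Functional wrapper; builds a fresh block when none is supplied."""
    if block is None:
        block = SADBlock(cfg)
    return block(Tensor._coerce(x), domain)
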