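"""3D encoder-decoder segmentation network.

A UNet over (B, 1, D, H, W) volumes: scale-aware SAD blocks (or plain
domain-normalized double convolutions when disabled) in the encoder,
the global-local fusion block in the bottleneck, a plain convolutional
decoder with skip connections, and a softmax head over the five classes
(background + liver, right kidney, left kidney, spleen).

Every forward pass carries a domain tag; the tag only routes the
domain-specific batch-norm statistics — all convolution and transformer
weights are shared between domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, cat, no_grad
from .dsbn import ConvD, DomainSpecificBatchNorm3d
from .glf import GLFBlock, GLFConfig
from .nn import BatchNorm3d, Conv3d, Module, upsample_trilinear
from .sad import SADBlock, ScaleAwareConfig

__all__ = ["NetworkConfig", "SegNet", "build_network", "forward"]


@dataclass
class NetworkConfig:
    """Topology of the segmentation network.

    ``n_stages`` counts encoder resolutions including the bottleneck, so the
    input is downsampled ``n_stages - 1`` times; the deepest feature map must
    stay divisible by the GLF patch size.  ``base_width`` doubles per stage.
    """
    in_channels: int = 1
    n_classes: int = 5
    n_stages: int = 4
    base_width: int = 16
    use_sad: bool = True
    use_glf: bool = True
    dilation_rates: tuple[int, int] = (1, 3)
    se_reduction: int = 4
    glf_depth: int = 4
    glf_d_head: int = 8
    glf_patch: tuple[int, int, int] = (2, 2, 2)
    decoder_double_conv: bool = True
    dsbn_decoder: bool = False     # domain-specific normalization in the decoder too
    input_noise_sd: float = 0.05   # Gaussian perturbation used for consistency noise

    @property
    def widths(self) -> list[int]:
        return [self.base_width * 2 ** i for i in range(self.n_stages)]

    def validate(self) -> None:
        if self.n_stages < 2:
            raise ValueError("need at least two stages (one skip + bottleneck)")
        if self.base_width % 2:
            raise ValueError("base_width must be even")
        deep = self.widths[-1]
        if self.use_glf and (deep // 2) % self.glf_d_head:
            raise ValueError(
                f"bottleneck width {deep} gives transformer width {deep // 2}, "
                f"not divisible by d_head={self.glf_d_head}")


class _EncoderStage(Module):
    domain_aware = True

    def __init__(self, in_ch: int, out_ch: int, cfg: NetworkConfig, rng):
        super().__init__()
        if cfg.use_sad:
            sad_cfg = ScaleAwareConfig(in_channels=in_ch, out_channels=out_ch,
                                       dilation_rates=cfg.dilation_rates,
                                       se_reduction=cfg.se_reduction)
            self.block = SADBlock(sad_cfg, rng=rng)
        else:
            self.block = _DoubleConvD(in_ch, out_ch, rng)

    def forward(self, x, domain):
        return self.block(x, domain)


class _DoubleConvD(Module):
    domain_aware = True

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.c1 = ConvD(in_ch, out_ch, rng=rng)
        self.c2 = ConvD(out_ch, out_ch, rng=rng)

    def forward(self, x, domain):
        return self.c2(self.c1(x, domain), domain)


class _DecoderStage(Module):
    """Upsample x2, halve width, concat skip, conv-norm-ReLU block(s).

    Normalization is plain batch norm by default; with ``dsbn`` the decoder
    becomes domain-aware like the encoder (useful when mixed-domain training
    would otherwise blend running statistics)."""

    domain_aware = True

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, rng,
                 double: bool = True, dsbn: bool = False):
        super().__init__()
        self.double = double
        self.dsbn = dsbn
        norm = DomainSpecificBatchNorm3d if dsbn else BatchNorm3d
        self.up_conv = Conv3d(in_ch, out_ch, 3, bias=False, rng=rng)
        self.up_norm = norm(out_ch)
        self.c1 = Conv3d(out_ch + skip_ch, out_ch, 3, bias=False, rng=rng)
        self.n1 = norm(out_ch)
        if double:
            self.c2 = Conv3d(out_ch, out_ch, 3, bias=False, rng=rng)
            self.n2 = norm(out_ch)

    def _norm(self, layer, x, domain):
        return layer(x, domain) if self.dsbn else layer(x)

    def forward(self, x, skip, domain):
        x = self._norm(self.up_norm, self.up_conv(upsample_trilinear(x)),
                       domain).relu()
        x = cat([x, skip], axis=1)
        x = self._norm(self.n1, self.c1(x), domain).relu()
        if self.double:
            x = self._norm(self.n2, self.c2(x), domain).relu()
        return x


class SegNet(Module):
    """The assembled student/teacher network; see module docstring."""

    domain_aware = True

    def __init__(self, cfg: NetworkConfig, seed: int | None = None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.widths
        n_enc = cfg.n_stages - 1       # stages that leave a skip connection
        for i in range(n_enc):
            in_ch = cfg.in_channels if i == 0 else widths[i]
            setattr(self, f"enc_{i}", _EncoderStage(in_ch, widths[i], cfg, rng))
            setattr(self, f"down_{i}", ConvD(widths[i], widths[i + 1], stride=2, rng=rng))
        deep = widths[-1]
        if cfg.use_glf:
            glf_cfg = GLFConfig(in_channels=deep, out_channels=deep,
                                patch=cfg.glf_patch, depth=cfg.glf_depth,
                                d_head=cfg.glf_d_head)
            self.bottleneck = GLFBlock(glf_cfg, rng=rng)
            self._bottleneck_domain_aware = False
        else:
            self.bottleneck = _DoubleConvD(deep, deep, rng)
            self._bottleneck_domain_aware = True
        for i in reversed(range(n_enc)):
            setattr(self, f"dec_{i}",
                    _DecoderStage(widths[i + 1], widths[i], widths[i], rng,
                                  double=cfg.decoder_double_conv,
                                  dsbn=cfg.dsbn_decoder))
        self.head = Conv3d(widths[0], cfg.n_classes, 1, rng=rng)

    def forward(self, x, domain: str) -> Tensor:
        """Return per-voxel class probabilities (B, n_classes, D, H, W)."""
        x = Tensor._coerce(x)
        if x.ndim != 5:
            raise ValueError(f"expected a (B,C,D,H,W) batch, got shape {x.shape}")
        for name, n in zip("DHW", x.shape[2:]):
            if n % 2 ** (self.cfg.n_stages - 1):
                raise ValueError(
                    f"axis {name} (size {n}) not divisible by the total downsampling "
                    f"factor {2 ** (self.cfg.n_stages - 1)}")
        skips = []
        n_enc = self.cfg.n_stages - 1
        for i in range(n_enc):
            x = getattr(self, f"enc_{i}")(x, domain)
            skips.append(x)
            x = getattr(self, f"down_{i}")(x, domain)
        if self._bottleneck_domain_aware:
            x = self.bottleneck(x, domain)
        else:
            x = self.bottleneck(x)
        for i in reversed(range(n_enc)):
            x = getattr(self, f"dec_{i}")(x, skips[i], domain)
        return self.head(x).softmax(axis=1)


def build_network(cfg: NetworkConfig, seed: int | None = None) -> SegNet:
    """Construct a network; two calls with the same seed give identical weights."""
    return SegNet(cfg, seed=seed)


def forward(model: SegNet, x, domain: str, *, noise_sd: float = 0.0,
            rng: np.random.Generator | None = None, grad: bool = True) -> Tensor:
    """Run a (possibly input-perturbed) forward pass.

    ``noise_sd > 0`` adds i.i.d. Gaussian noise to the input before the
    network — the perturbation the consistency loss compares across
    student and teacher.  ``grad=False`` runs without building a tape
    (teacher passes).
    """
    x = np.asarray(x.data if isinstance(x, Tensor) else x, dtype=np.float32)
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng for the noise draw")
        x = x + rng.normal(0.0, noise_sd, size=x.shape).astype(np.float32)
    if grad:
        return model(Tensor(x), domain)
    with no_grad():
        return model(Tensor(x), domain)
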