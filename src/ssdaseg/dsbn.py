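"""Domain-specific batch normalization (DSBN).

Multi-modal training batches drawn from different scanners or modalities
have per-domain intensity statistics; normalizing them with one shared
set of batch-norm statistics washes the domain structure into the affine
parameters and hurts both domains.  DSBN keeps one complete batch-norm
state per domain — running mean/variance *and* the learned scale/shift —
and routes every forward pass through the state selected by the sample's
domain tag.  All convolutional weights around it stay shared, so the
network learns domain-invariant filters on domain-normalized features.

Every mini-batch entering a DSBN layer must be single-domain; mixed
batches are split by the trainer before the forward pass.
"""

from __future__ import annotations

from ._tensor import Tensor
from .nn import BatchNorm3d, Conv3d, Module

__all__ = ["DOMAINS", "DomainSpecificBatchNorm3d", "ConvD", "dsbn_forward"]

DOMAINS = ("source", "target")


class DomainSpecificBatchNorm3d(Module):
    """One :class:`~ssdaseg.nn.BatchNorm3d` per domain, selected per call.

    Parameters and running statistics of the two domains live in disjoint
    storage: a forward/update pass tagged ``target`` cannot touch anything
    belonging to ``source``, and vice versa.
    """

    domain_aware = True

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        for d in DOMAINS:
            setattr(self, f"bn_{d}", BatchNorm3d(num_features, eps=eps, momentum=momentum))

    def branch(self, domain: str) -> BatchNorm3d:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain tag {domain!r}; expected one of {DOMAINS}")
        return getattr(self, f"bn_{domain}")

    def forward(self, x: Tensor, domain: str) -> Tensor:
        return self.branch(domain)(x)


def dsbn_forward(x, domain: str, state: DomainSpecificBatchNorm3d,
                 training: bool = True) -> Tensor:
    """Functional entry point: normalize ``x`` with the given domain's statistics.

    ``training=True`` standardizes with mini-batch statistics and updates that
    domain's running statistics; ``training=False`` uses the stored running
    statistics and leaves the state untouched.
    """
    prev = state.training
    state.train(training)
    try:
        return state(Tensor._coerce(x), domain)
    finally:
        state.train(prev)


class ConvD(Module):
    """Conv-D: 3D convolution -> DSBN -> ReLU, the domain-aware convolution block."""

    domain_aware = True

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3, *,
                 stride: int = 1, dilation: int = 1, rng=None):
        super().__init__()
        self.conv = Conv3d(in_channels, out_channels, kernel_size, stride=stride,
                           dilation=dilation, bias=False, rng=rng)
        self.norm = DomainSpecificBatchNorm3d(out_channels)

    def forward(self, x: Tensor, domain: str) -> Tensor:
        return self.norm(self.conv(x), domain).relu()
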