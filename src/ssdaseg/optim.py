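"""AdamW with decoupled weight decay, stepwise-exponential LR, gradient clipping."""

from __future__ import annotations

import math

import numpy as np

from .nn import Parameter

__all__ = ["AdamW", "clip_grad_norm", "stepwise_exponential_lr"]


class AdamW:
    """Adam with decoupled weight decay (applied directly to the weights)."""

    def __init__(self, params: list[Parameter], lr: float = 9e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 5e-5):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = p.data - self.lr * (update + self.weight_decay * p.data)


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


def stepwise_exponential_lr(base_lr: float, iteration: int, gamma: float = 0.95,
                            every: int = 250) -> float:
    """LR used *at* 0-based ``iteration``: decayed by ``gamma`` every ``every`` steps."""
    return base_lr * gamma ** (iteration // every)
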