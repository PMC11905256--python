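"""Minimal neural-network layer library on top of :mod:`ssdaseg._tensor`.

Modules hold :class:`Parameter` leaves (learned) and plain-ndarray buffers
(running statistics, iteration counters).  ``state_dict`` /
``load_state_dict`` serialize both, which is what the teacher-student
machinery and checkpointing build on.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, axis_matmul, conv3d

__all__ = [
    "Parameter", "Module", "Sequential", "Conv3d", "Linear", "LayerNorm",
    "BatchNorm3d", "ReLU", "GELU", "upsample_trilinear",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Composable container of parameters, buffers and sub-modules."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # attribute routing ----------------------------------------------------
    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def set_buffer(self, name: str, value: np.ndarray) -> None:
        """Rebind a buffer (buffers are replaced, never mutated in place)."""
        if name not in self._buffers:
            raise KeyError(name)
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # traversal ------------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules():
            for p_name, p in mod._params.items():
                yield (f"{mod_name}.{p_name}" if mod_name else p_name, p)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for mod_name, mod in self.named_modules():
            for b_name in mod._buffers:
                yield (f"{mod_name}.{b_name}" if mod_name else b_name,
                       mod._buffers[b_name])

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = []
        for name, p in own.items():
            if name not in state:
                missing.append(name)
                continue
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{state[name].shape} vs {p.data.shape}")
            p.data = state[name].astype(p.data.dtype).copy()
        for mod_name, mod in self.named_modules():
            for b_name in list(mod._buffers):
                full = f"{mod_name}.{b_name}" if mod_name else b_name
                if full not in state:
                    missing.append(full)
                    continue
                mod.set_buffer(b_name, state[full].copy())
        if missing:
            raise ValueError(f"missing keys in state dict: {missing}")

    # modes ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x, **kwargs):
        for layer in self.layers:
            x = layer(x, **kwargs) if _accepts_kwargs(layer) else layer(x)
        return x


def _accepts_kwargs(layer: Module) -> bool:
    return getattr(layer, "domain_aware", False)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 *, stride: int = 1, padding: int | None = None, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.stride = stride
        self.dilation = dilation
        # 'same' padding for stride 1 by default
        self.padding = dilation * (k - 1) // 2 if padding is None else padding
        fan_in = in_channels * k ** 3
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(in_features, out_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalization over the last (feature) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.weight + self.bias


class BatchNorm3d(Module):
    """Batch normalization over (batch, spatial) per channel for 5D tensors.

    Training mode standardizes with mini-batch statistics and updates
    exponential running statistics; eval mode uses the stored ones and is
    side-effect free.  A training batch must contain at least two samples,
    otherwise the batch variance is undefined.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.num_features, 1, 1, 1)
        if self.training:
            if x.shape[0] < 2:
                raise ValueError(
                    "batch normalization in training mode needs a batch of >= 2 "
                    f"samples, got {x.shape[0]}")
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self.set_buffer("running_mean",
                            ((1 - m) * self.running_mean
                             + m * mu.data.reshape(-1)).astype(np.float32))
            self.set_buffer("running_var",
                            ((1 - m) * self.running_var
                             + m * var.data.reshape(-1)).astype(np.float32))
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            centered = x - mu
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.weight.reshape(shape) + self.bias.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


def _linear_upsample_matrix(n: int, dtype=np.float32) -> np.ndarray:
    """Length-doubling linear interpolation matrix (edge-clamped, centers aligned)."""
    m = np.zeros((2 * n, n), dtype=dtype)
    for j in range(2 * n):
        src = (j + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        m[j, lo_c] += 1.0 - frac
        m[j, hi_c] += frac
    return m


def upsample_trilinear(x: Tensor) -> Tensor:
    """Double each spatial dimension of a (B,C,D,H,W) tensor by linear interpolation."""
    for axis in (2, 3, 4):
        x = axis_matmul(x, _linear_upsample_matrix(x.shape[axis]), axis)
    return x
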