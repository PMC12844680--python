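"""Layer/module abstractions over the autodiff tensor primitives.

Modules own :class:`Parameter` tensors, expose ``parameters()`` /
``state_dict()`` by dotted name, and are constructed with an explicit
``numpy.random.Generator`` so that model builds are reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from .tensor import (
    Tensor,
    conv2d,
    depthwise_conv2d,
    gelu,
    layer_norm_channels,
)

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "DepthwiseConv2d",
    "Linear",
    "LayerNormChannels",
    "GELU",
    "Identity",
    "Sequential",
    "trunc_normal",
    "he_normal",
]


def trunc_normal(shape, std: float, rng: np.random.Generator) -> np.ndarray:
    """Normal(0, std) truncated at +/-2 std (the ConvNeXt init convention)."""
    flat = truncnorm.rvs(-2.0, 2.0, scale=std, size=int(np.prod(shape)),
                         random_state=rng)
    return flat.astype(np.float32).reshape(shape)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; children registered as attributes are discovered recursively."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(unexpected)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self._items = list(modules)

    def append(self, module):
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def named_parameters(self, prefix: str = ""):
        for i, module in enumerate(self._items):
            sub = f"{prefix}.{i}" if prefix else str(i)
            yield from module.named_parameters(sub)


def he_normal(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """Fan-in-scaled normal init (preserves activation variance through convs)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator):
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_normal((out_ch, in_ch, kernel, kernel),
                                          fan_in, rng))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, *, padding: int = 0,
                 bias: bool = True, rng: np.random.Generator):
        self.padding = padding
        self.weight = Parameter(trunc_normal((channels, kernel, kernel), 0.02, rng))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 bias: bool = True, rng: np.random.Generator):
        self.weight = Parameter(he_normal((in_features, out_features),
                                          in_features, rng))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNormChannels(Module):
    """LayerNorm across the channel axis of NC... tensors (per sample/position)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm_channels(x, self.gamma, self.beta, eps=self.eps)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return gelu(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *modules):
        self._items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for module in self._items:
            x = module(x)
        return x

    def named_parameters(self, prefix: str = ""):
        for i, module in enumerate(self._items):
            sub = f"{prefix}.{i}" if prefix else str(i)
            yield from module.named_parameters(sub)
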