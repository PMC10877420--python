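"""Layers and parameter containers on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = ["Module", "Parameter", "Conv2d", "Linear", "GroupNorm", "Sequential"]


class Parameter(Tensor):
    """A tensor that is optimized during training."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive discovery, torch-style."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        if c_in % groups or c_out % groups:
            raise ValueError(f"channels ({c_in}->{c_out}) not divisible by groups={groups}")
        rng = rng or np.random.default_rng()
        fan_in = (c_in // groups) * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init
        self.weight = Parameter(rng.normal(0.0, scale, (c_out, c_in // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding, groups=self.groups)

    def zero_(self):
        """Zero the learned operator (used for identity/ablation checks)."""
        self.weight.data[:] = 0.0
        if self.bias is not None:
            self.bias.data[:] = 0.0
        return self


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class GroupNorm(Module):
    """Group normalization with learned per-channel scale gamma and shift beta.

    Normalizes each (sample, channel-group) slice to zero mean / unit
    variance, then applies y = gamma * xhat + beta.  The gamma magnitudes
    double as the channel-informativeness signal used by the spatial
    reconstruction unit.
    """

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError(
                f"channels ({num_channels}) not divisible by groups ({num_groups})")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = float(eps)
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.num_channels:
            raise ValueError(f"expected {self.num_channels} channels, got {c}")
        g = self.num_groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xhat = (xg - mu) / (var + self.eps).sqrt()
        xhat = xhat.reshape(n, c, h, w)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x) if isinstance(m, Module) else m(x)
        return x
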