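"""Layers, parameter containers and the Adam optimizer.

Weight initialization is Kaiming fan-in scaling driven by an explicit
``numpy.random.Generator``; every model takes its generator from one seed
authority so that two builds from the same seed have identical weights.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "Adam", "activation"]


class Module:
    """Parameter container with recursive traversal (no forward contract)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ConfigurationError(
                f"checkpoint holds {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ConfigurationError(
                    f"shape mismatch loading weights: {p.data.shape} vs {a.shape}"
                )
            p.data = np.asarray(a, dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (e.g. float32 for faster training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


class Conv2d(Module):
    """3x3 (or kxk) convolution with "same" spatial size at stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *,
                 stride: int = 1, padding: str = "reflect",
                 rng: np.random.Generator, zero_init: bool = False):
        if kernel % 2 != 1:
            raise ConfigurationError("conv kernel size must be odd")
        fan_in = in_ch * kernel * kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.standard_normal((in_f, out_f)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def activation(x: Tensor, kind: str) -> Tensor:
    """Apply a named activation (``elu`` or ``sigmoid``)."""
    if kind == "elu":
        return x.elu()
    if kind == "sigmoid":
        return x.sigmoid()
    raise ConfigurationError(f"unknown activation {kind!r}")


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
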