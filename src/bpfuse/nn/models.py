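"""Generator and discriminator architectures.

Generator (two-branch, fully convolutional, stride 1 throughout, so H x W
is preserved end to end):

    each branch:  conv-ELU x2  ->  BPDB  ->  CBAM        (base channels C)
    merge:        channel concat (2C)  ->  BPDB  ->  CBAM
    head:         conv-ELU (2C -> C)  ->  conv (C -> 1)  ->  sigmoid

The two branches have independent weights.  The final sigmoid guarantees
fused intensities in [0, 1], matching the [0, 1] inputs the content losses
compare against.

Discriminator: operates on gradient maps, not images.  A stack of stride-2
3x3 conv-ELU layers (default 1->16->32->64->64), global average pooling and
a single logistic unit produce one probability per sample — the belief that
the input is a *joint* gradient map of two sources rather than the gradient
map of a generated fusion.

All widths/depths are config-driven; the defaults are sized for CPU use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, InvalidInputError
from .autograd import Tensor, concat, conv2d
from .blocks import BPDB, CBAM, ConvAct, Identity
from .layers import Conv2d, Linear, Module

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "Generator", "Discriminator"]


@dataclass(frozen=True)
class GeneratorConfig:
    base_channels: int = 32
    conv_kernel: int = 3
    activation: str = "elu"
    attention_gate: str = "elu"       # gate nonlinearity inside CBAM
    cbam_reduction: int = 8
    use_bpdb: bool = True             # ablation switches; Identity when off
    use_cbam: bool = True

    def __post_init__(self):
        if self.base_channels < 4:
            raise ConfigurationError("base_channels must be >= 4")
        if self.conv_kernel % 2 != 1:
            raise ConfigurationError("conv_kernel must be odd")


@dataclass(frozen=True)
class DiscriminatorConfig:
    channel_schedule: tuple[int, ...] = (16, 32, 64, 64)
    use_spectral_norm: bool = False
    activation: str = "elu"

    def __post_init__(self):
        if len(self.channel_schedule) == 0:
            raise ConfigurationError("channel_schedule must be non-empty")


class _Branch(Module):
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        c, k, a = cfg.base_channels, cfg.conv_kernel, cfg.activation
        self.ext1 = ConvAct(1, c, k, act=a, rng=rng)
        self.ext2 = ConvAct(c, c, k, act=a, rng=rng)
        self.bpdb = (BPDB(c, k, act=a, rng=rng) if cfg.use_bpdb else Identity())
        self.cbam = (CBAM(c, reduction=cfg.cbam_reduction,
                          gate=cfg.attention_gate, rng=rng)
                     if cfg.use_cbam else Identity())

    def __call__(self, x: Tensor) -> Tensor:
        return self.cbam(self.bpdb(self.ext2(self.ext1(x))))


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig = GeneratorConfig(), *,
                 rng: np.random.Generator):
        self.cfg = cfg
        c, k, a = cfg.base_channels, cfg.conv_kernel, cfg.activation
        self.branch_m = _Branch(cfg, rng)     # structural (MRI/CT) branch
        self.branch_y = _Branch(cfg, rng)     # functional luminance branch
        self.comp_bpdb = (BPDB(2 * c, k, act=a, rng=rng)
                          if cfg.use_bpdb else Identity())
        self.comp_cbam = (CBAM(2 * c, reduction=cfg.cbam_reduction,
                               gate=cfg.attention_gate, rng=rng)
                          if cfg.use_cbam else Identity())
        self.head1 = ConvAct(2 * c, c, k, act=a, rng=rng)
        self.head2 = Conv2d(c, 1, k, rng=rng)

    def __call__(self, m: Tensor, y: Tensor) -> Tensor:
        if m.shape != y.shape:
            raise InvalidInputError(
                f"branch inputs differ in shape: {m.shape} vs {y.shape}"
            )
        fm = self.branch_m(m)
        fy = self.branch_y(y)
        fused = concat([fm, fy], axis=1)
        enhanced = self.comp_cbam(self.comp_bpdb(fused))
        return self.head2(self.head1(enhanced)).sigmoid()

    def fuse(self, m: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Fuse one co-registered grayscale pair (numpy in, numpy out)."""
        m = np.asarray(m, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if m.shape != y.shape or m.ndim != 2:
            raise InvalidInputError(
                f"expected two equal 2-D images, got {m.shape} and {y.shape}"
            )
        out = self(Tensor(m[None, None]), Tensor(y[None, None]))
        return out.data[0, 0]


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig = DiscriminatorConfig(), *,
                 rng: np.random.Generator):
        self.cfg = cfg
        chans = [1, *cfg.channel_schedule]
        self.convs = [
            Conv2d(ci, co, 3, stride=2, padding="zero", rng=rng)
            for ci, co in zip(chans[:-1], chans[1:])
        ]
        self.fc = Linear(cfg.channel_schedule[-1], 1, rng=rng)
        # persistent power-iteration vectors, one per conv (spectral norm)
        self._u = [rng.standard_normal(c.weight.data.shape[0])
                   for c in self.convs]

    def _sn_weight(self, i: int) -> Tensor:
        """Weight of conv ``i`` scaled by 1/sigma (sigma detached)."""
        layer = self.convs[i]
        wmat = layer.weight.data.reshape(layer.weight.data.shape[0], -1)
        u = self._u[i]
        v = wmat.T @ u
        v /= np.linalg.norm(v) + 1e-12
        u = wmat @ v
        sigma = np.linalg.norm(u) + 1e-12
        self._u[i] = u / sigma
        return layer.weight * (1.0 / sigma)

    def __call__(self, g: Tensor) -> Tensor:
        """Score a batch of gradient maps; returns (N,) probabilities."""
        if not np.all(np.isfinite(g.data)):
            raise InvalidInputError("discriminator input contains non-finite values")
        x = g
        for i, layer in enumerate(self.convs):
            if self.cfg.use_spectral_norm:
                x = conv2d(x, self._sn_weight(i), layer.bias,
                           stride=2, padding="zero")
            else:
                x = layer(x)
            x = x.elu()
        pooled = x.mean(axis=(2, 3))          # global average pooling
        return self.fc(pooled).sigmoid().reshape(-1)

    def score(self, grad_map: np.ndarray) -> float:
        """Numpy convenience: probability that one map is a joint-gradient map."""
        arr = np.asarray(grad_map, dtype=np.float64)
        if arr.ndim != 2:
            raise InvalidInputError(f"expected a 2-D gradient map, got {arr.shape}")
        return float(self(Tensor(arr[None, None])).data[0])
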