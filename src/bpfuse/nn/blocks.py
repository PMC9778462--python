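"""Back-project dense block (BPDB) and convolutional block attention (CBAM).

Both blocks preserve the channel count and spatial size of their input.

The BPDB targets the large black backgrounds typical of functional
modalities: it re-encodes features, measures what a further
convolution-activation *changes* about them (the back-projection
difference), folds that correction back in, and finally reconstructs from
the absolute residual so that flat background regions — where the
difference is near zero — contribute little to the output.  Three stages:

* enhance:     ``F_enc = enc(x)``; ``d = diff(F_enc) - F_enc``;
               ``F_add = dec(F_enc + d)``
* residual:    ``F_res = dec(|diff(F_add) - F_add|)``
* reconstruct: ``out = dec(enc(F_res) + F_add)``

CBAM applies channel attention (max- and average-pooled descriptors
through a shared bottleneck MLP) followed by spatial attention (channelwise
max/average maps through a 1x1 convolution); both gates multiply the
features.  The gate activation is ELU by default with a conventional
sigmoid option.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from .autograd import Tensor, concat
from .layers import Conv2d, Linear, Module, activation

__all__ = ["ConvAct", "BPDB", "CBAM", "Identity"]


class Identity(Module):
    """Pass-through stand-in used by the ablation switches."""

    def __call__(self, x: Tensor) -> Tensor:
        return x


class ConvAct(Module):
    """Convolution followed by the configured activation (default ELU)."""

    def __init__(self, in_ch, out_ch, kernel=3, *, act="elu",
                 rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, kernel, rng=rng)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        return activation(self.conv(x), self.act)


class BPDB(Module):
    def __init__(self, channels: int, kernel: int = 3, *, act: str = "elu",
                 rng: np.random.Generator):
        mk = lambda: ConvAct(channels, channels, kernel, act=act, rng=rng)
        self.enc = mk()
        self.diff_enh = mk()
        self.dec_enh = mk()
        self.diff_res = mk()
        self.dec_res = mk()
        self.enc_rec = mk()
        self.dec_rec = mk()
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"BPDB configured for {self.channels} channels, got {x.shape[1]}"
            )
        f_enc = self.enc(x)
        d = self.diff_enh(f_enc) - f_enc
        f_add = self.dec_enh(f_enc + d)
        f_res = self.dec_res((self.diff_res(f_add) - f_add).abs())
        return self.dec_rec(self.enc_rec(f_res) + f_add)

    def forward_array(self, f_pre: np.ndarray) -> np.ndarray:
        """Numpy convenience: run one C x H x W feature map through the block."""
        out = self(Tensor(np.asarray(f_pre, dtype=np.float64)[None]))
        return out.data[0]


class CBAM(Module):
    def __init__(self, channels: int, *, reduction: int = 8,
                 gate: str = "elu", rng: np.random.Generator):
        if channels < 2:
            raise ConfigurationError("CBAM needs at least 2 channels")
        hidden = max(channels // reduction, 1)
        # shared bottleneck MLP applied to both pooled descriptors
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.spatial_conv = Conv2d(2, 1, kernel=1, rng=rng)
        self.gate = gate
        self.channels = channels
        # pass-through start: zero the last gate layers and pick the bias so
        # the gate opens at 1 (ELU) or 1/2 (sigmoid); with an unbounded ELU
        # gate this keeps multiplicative stacks from exploding at init
        self.fc2.weight.data[:] = 0.0
        self.spatial_conv.weight.data[:] = 0.0
        if gate == "elu":
            self.fc2.bias.data[:] = 0.5
            self.spatial_conv.bias.data[:] = 1.0

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).elu())

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"CBAM configured for {self.channels} channels, got {x.shape[1]}"
            )
        n, c = x.shape[0], x.shape[1]
        # channel attention from max- and average-pooled descriptors
        fmax = x.max(axis=(2, 3))
        favg = x.mean(axis=(2, 3))
        cgate = activation(self._mlp(fmax) + self._mlp(favg), self.gate)
        x1 = x * cgate.reshape(n, c, 1, 1)
        # spatial attention from channelwise max and average maps
        smax = x1.max(axis=1, keepdims=True)
        savg = x1.mean(axis=1, keepdims=True)
        sgate = activation(self.spatial_conv(concat([smax, savg], axis=1)),
                           self.gate)
        return x1 * sgate

    def forward_array(self, f: np.ndarray) -> np.ndarray:
        out = self(Tensor(np.asarray(f, dtype=np.float64)[None]))
        return out.data[0]
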