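"""Minimal reverse-mode automatic differentiation over numpy arrays.

The fusion networks are small stride-1 convolutional stacks, so rather than
depend on a full deep-learning framework the package carries its own
compact tape-based autograd: a :class:`Tensor` wraps an ``ndarray``,
records the operations applied to it, and :meth:`Tensor.backward` walks the
tape in reverse topological order accumulating gradients.

Only the ops the fusion models need are implemented: broadcasting
arithmetic, ``abs``/``maximum``, ELU and logistic activations, matrix
multiply, reductions, channel concatenation, spatial max/mean pooling, and
2-D convolution (stride >= 1, zero or edge-mirrored "same" padding) via an
im2col/col2im pair that routes the inner products through BLAS.

Everything is float64 and deterministic: identical inputs and weights give
bit-identical outputs and gradients, which is what makes the training-loop
reproducibility contract testable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "maximum", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape machinery for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._prev:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities --------------------------------------

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def elu(self, alpha: float = 1.0):
        neg = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(self.data > 0, self.data, neg)
        out = Tensor(out_data, _prev=(self,))
        grad_mask = np.where(self.data > 0, 1.0, neg + alpha)
        out._backward = lambda g: self._accumulate(g * grad_mask)
        return out

    def sigmoid(self):
        # numerically stable logistic
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    # -- reductions and shaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        """Max-reduction; ties share the incoming gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        out = Tensor(m if keepdims else np.squeeze(m, axis=axis), _prev=(self,))
        mask = (self.data == m).astype(self.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (channel axis 1 for feature maps)."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max of two tensors; ties split the gradient equally."""
    out = Tensor(np.maximum(a.data, b.data), _prev=(a, b))
    dt = a.data.dtype
    ga = np.where(a.data > b.data, dt.type(1.0),
                  np.where(a.data == b.data, dt.type(0.5), dt.type(0.0)))

    def bwd(g):
        a._accumulate(_unbroadcast(g * ga, a.data.shape))
        b._accumulate(_unbroadcast(g * (1.0 - ga), b.data.shape))

    out._backward = bwd
    return out


# -- 2-D convolution ------------------------------------------------------

def _pad_input(x: np.ndarray, pad: int, mode: str):
    """Pad spatial dims; returns padded array and an index map for backward."""
    if pad == 0:
        return x, None
    if mode == "zero":
        return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))), None
    if mode == "reflect":
        # edge-mirrored (symmetric) padding, matching scipy mode="reflect"
        h, w = x.shape[2], x.shape[3]
        idx = np.pad(
            np.arange(h * w).reshape(h, w),
            pad, mode="symmetric",
        )
        xp = x.reshape(*x.shape[:2], h * w)[..., idx]
        return xp, idx
    raise ValueError(f"unknown padding mode {mode!r}")


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: int = 1,
    padding: str = "reflect",
) -> Tensor:
    """Batched 2-D cross-correlation.

    Parameters
    ----------
    x : Tensor, shape (N, C, H, W)
    w : Tensor, shape (O, C, kh, kw)
    b : Tensor or None, shape (O,)
    stride : int
    padding : {"reflect", "zero", "valid"}
        "Same" padding of ``k // 2`` with the given boundary rule, or no
        padding at all ("valid").
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    pad = 0 if padding == "valid" else kh // 2
    mode = "zero" if padding in ("zero", "valid") else "reflect"
    xp, idx = _pad_input(x.data, pad, mode)
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    # im2col -> (N*Ho*Wo, C*kh*kw); inner products run as one BLAS gemm.
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                     # N,C,Ho,Wo,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(w.data.shape[0], c * kh * kw)
    out_data = (cols @ wmat.T).reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, -1)   # (NHoWo, O)
        if w.requires_grad or w._prev:
            w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._prev):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gcols = gmat @ wmat                                   # (NHoWo, Ckhkw)
            gcols = gcols.reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if pad == 0:
                gx = gxp
            elif mode == "zero":
                gx = gxp[:, :, pad:-pad, pad:-pad]
            elif pad == 1:
                # symmetric pad of 1: border pixels receive their mirror's
                # gradient; slice adds beat a generic scatter by a lot
                gx = np.ascontiguousarray(gxp[:, :, 1:-1, 1:-1])
                gx[:, :, 0, :] += gxp[:, :, 0, 1:-1]
                gx[:, :, -1, :] += gxp[:, :, -1, 1:-1]
                gx[:, :, :, 0] += gxp[:, :, 1:-1, 0]
                gx[:, :, :, -1] += gxp[:, :, 1:-1, -1]
                gx[:, :, 0, 0] += gxp[:, :, 0, 0]
                gx[:, :, 0, -1] += gxp[:, :, 0, -1]
                gx[:, :, -1, 0] += gxp[:, :, -1, 0]
                gx[:, :, -1, -1] += gxp[:, :, -1, -1]
            else:  # scatter mirrored border gradients back to source pixels
                h, wd = x.data.shape[2], x.data.shape[3]
                flat = np.zeros((n * c, h * wd), dtype=g.dtype)
                np.add.at(
                    flat,
                    (np.arange(n * c)[:, None], idx.ravel()[None, :]),
                    gxp.reshape(n * c, -1),
                )
                gx = flat.reshape(x.data.shape)
            x._accumulate(gx)

    out._backward = bwd
    return out
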