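"""The loss suite: adversarial, screened pixel, screened gradient terms.

Generator loss
    L = L_Gan + lambda1 * L_pixel + lambda2 * L_grad

* ``L_Gan``  — least-squares adversarial term ``mean((D(|lap F|) - c)^2)``
  with generator target ``c = 1``; the squared form keeps gradients alive
  where the saturating log form would stall early in training.
* ``L_pixel`` — screened mean squared intensity distance to the two inputs.
* ``L_grad``  — the same screening applied to Laplacian responses, pulling
  the fused texture toward whichever input is locally sharper.

Discriminator loss
    L_D = mean((D(Grad1) - a)^2 + (D(Grad2) - b)^2),   a = 0, b = 1

where ``Grad1`` is the fused image's absolute Laplacian ("false" data) and
``Grad2`` the inputs' joint gradient map ("real" data).

Screening maps.  ``Map1``/``Map2`` are complementary per-pixel weights that
decide which input each fused pixel should resemble.  They are computed
once per image pair by comparing local saliency — windowed variance in a
``window x window`` neighbourhood (default 7) — of the two inputs: where
the structural image is locally busier its weight is 1, where the
companion is busier it is 0, and exact ties split 50/50.  A constant-0.5
mode is available as a saliency-free fallback.

Every function here accepts either numpy arrays or autograd
:class:`~bpfuse.nn.autograd.Tensor` values for the *fused* image and the
discriminator scores, so the same definitions serve both evaluation and
backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .gradients import laplacian, laplacian_kernel
from .nn.autograd import Tensor, conv2d
from .types import check_same_shape

__all__ = [
    "ScreeningMaps", "LossWeights", "AdversarialLabels",
    "screening_maps", "windowed_variance",
    "adversarial_loss", "pixel_loss", "gradient_loss",
    "generator_total", "discriminator_loss", "calibrate_weights",
]


@dataclass(frozen=True)
class ScreeningMaps:
    """Complementary per-pixel weights; ``map1 + map2 == 1`` everywhere."""

    map1: np.ndarray
    map2: np.ndarray

    def __post_init__(self):
        check_same_shape(self.map1, self.map2, names="screening maps")
        if self.map1.min() < 0 or self.map1.max() > 1:
            raise InvalidInputError("map1 values must lie in [0, 1]")
        if not np.allclose(self.map1 + self.map2, 1.0):
            raise InvalidInputError("screening maps must sum to 1 elementwise")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the pixel and gradient terms in the generator loss."""

    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise InvalidInputError("loss weights must be finite")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise InvalidInputError("loss weights must be non-negative")


@dataclass(frozen=True)
class AdversarialLabels:
    a: float = 0.0   # "false data" label (fused gradient map)
    b: float = 1.0   # "true data" label (joint gradient map)
    c: float = 1.0   # generator's target score

    def __post_init__(self):
        if not self.a < self.b:
            raise InvalidInputError("labels require a < b")


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _mean(x):
    return x.mean() if _is_tensor(x) else float(np.mean(x))


def windowed_variance(img: np.ndarray, window: int) -> np.ndarray:
    """Local variance in a ``window x window`` neighbourhood (mirrored edges)."""
    img = np.asarray(img, dtype=np.float64)
    mu = ndimage.uniform_filter(img, size=window, mode="reflect")
    mu2 = ndimage.uniform_filter(img * img, size=window, mode="reflect")
    return np.maximum(mu2 - mu * mu, 0.0)


def screening_maps(
    m: np.ndarray,
    i: np.ndarray,
    window: int = 7,
    mode: str = "variance",
) -> ScreeningMaps:
    """Build the judgment-block weights from local saliency of the inputs."""
    m = np.asarray(m, dtype=np.float64)
    i = np.asarray(i, dtype=np.float64)
    check_same_shape(m, i, names="screening inputs")
    if mode == "constant":
        half = np.full(m.shape, 0.5)
        return ScreeningMaps(map1=half, map2=half.copy())
    if mode != "variance":
        raise InvalidInputError(f"unknown screening mode {mode!r}")
    if window < 3 or window % 2 == 0:
        raise InvalidInputError("screening window must be odd and >= 3")
    vm = windowed_variance(m, window)
    vi = windowed_variance(i, window)
    map1 = np.where(vm > vi, 1.0, np.where(vm < vi, 0.0, 0.5))
    return ScreeningMaps(map1=map1, map2=1.0 - map1)


def adversarial_loss(d_scores, labels: AdversarialLabels = AdversarialLabels()):
    """Least-squares generator adversarial term ``mean((D - c)^2)``."""
    if _is_tensor(d_scores):
        if d_scores.data.size == 0:
            raise InvalidInputError("empty score batch")
        return ((d_scores - labels.c) ** 2).mean()
    scores = np.asarray(d_scores, dtype=np.float64)
    if scores.size == 0:
        raise InvalidInputError("empty score batch")
    return float(np.mean((scores - labels.c) ** 2))


def pixel_loss(fused, m: np.ndarray, i: np.ndarray, maps: ScreeningMaps):
    """Screened mean squared intensity distance of the fusion to its inputs."""
    m = np.asarray(m, dtype=np.float64)
    i = np.asarray(i, dtype=np.float64)
    shape = fused.data.shape[-2:] if _is_tensor(fused) else np.shape(fused)
    if shape != m.shape or m.shape != i.shape or maps.map1.shape != m.shape:
        raise InvalidInputError("pixel_loss inputs must share one shape")
    if _is_tensor(fused):
        return (maps.map1 * (fused - m) ** 2
                + maps.map2 * (fused - i) ** 2).mean()
    fused = np.asarray(fused, dtype=np.float64)
    return float(np.mean(maps.map1 * (fused - m) ** 2
                         + maps.map2 * (fused - i) ** 2))


def _laplacian_tensor(x: Tensor, kernel: str) -> Tensor:
    """Laplacian of an (N, 1, H, W) tensor inside the autograd graph."""
    k = laplacian_kernel(kernel)[::-1, ::-1]  # correlate == convolve (symmetric kernel)
    w = Tensor(k[None, None].astype(x.data.dtype))
    return conv2d(x, w, None, stride=1, padding="reflect")


def gradient_loss(fused, m: np.ndarray, y: np.ndarray, maps: ScreeningMaps,
                  kernel: str = "4"):
    """Screened mean squared Laplacian distance of the fusion to its inputs."""
    m = np.asarray(m, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lap_m = laplacian(m, kernel)
    lap_y = laplacian(y, kernel)
    if _is_tensor(fused):
        if fused.data.shape[-2:] != m.shape:
            raise InvalidInputError("gradient_loss inputs must share one shape")
        lap_f = _laplacian_tensor(fused, kernel)
        return (maps.map1 * (lap_f - lap_m) ** 2
                + maps.map2 * (lap_f - lap_y) ** 2).mean()
    fused = np.asarray(fused, dtype=np.float64)
    check_same_shape(fused, m, y, maps.map1, names="gradient_loss inputs")
    lap_f = laplacian(fused, kernel)
    return float(np.mean(maps.map1 * (lap_f - lap_m) ** 2
                         + maps.map2 * (lap_f - lap_y) ** 2))


def generator_total(lgan, lpix, lgrad, w: LossWeights = LossWeights()):
    """Total generator objective ``L_Gan + lambda1 L_pixel + lambda2 L_grad``."""
    return lgan + w.lambda1 * lpix + w.lambda2 * lgrad


def discriminator_loss(scores_false, scores_true,
                       labels: AdversarialLabels = AdversarialLabels()):
    """Least-squares discriminator objective over paired false/true batches."""
    tensor_path = _is_tensor(scores_false) or _is_tensor(scores_true)
    if tensor_path:
        nf = scores_false.data.size if _is_tensor(scores_false) else np.size(scores_false)
        nt = scores_true.data.size if _is_tensor(scores_true) else np.size(scores_true)
        if nf != nt:
            raise InvalidInputError("score batches must have equal length")
        if nf == 0:
            raise InvalidInputError("empty score batch")
        return (((scores_false - labels.a) ** 2).mean()
                + ((scores_true - labels.b) ** 2).mean())
    sf = np.asarray(scores_false, dtype=np.float64)
    st = np.asarray(scores_true, dtype=np.float64)
    if sf.size != st.size:
        raise InvalidInputError("score batches must have equal length")
    if sf.size == 0:
        raise InvalidInputError("empty score batch")
    return float(np.mean((sf - labels.a) ** 2 + (st - labels.b) ** 2))


def calibrate_weights(lgan: float, lpix: float, lgrad: float,
                      floor: float = 1e-8) -> LossWeights:
    """Rescale lambda1/lambda2 so the three terms match in magnitude.

    Intended to be called once on the first training batch; components at or
    below ``floor`` keep weight 1 (nothing meaningful to balance against).
    """
    l1 = lgan / lpix if lpix > floor and lgan > floor else 1.0
    l2 = lgan / lgrad if lgrad > floor and lgan > floor else 1.0
    return LossWeights(lambda1=float(l1), lambda2=float(l2))
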