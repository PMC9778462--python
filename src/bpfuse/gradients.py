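"""Laplacian gradient maps: the currency of the adversarial mechanism.

The discriminator never sees images — it sees gradient maps.  The "false"
sample is the absolute Laplacian of the fused image; the "real" sample is
the *joint* gradient map of the two inputs, i.e. the pixelwise maximum of
their absolute Laplacians.  During training the generator is pushed to make
the fused gradient map indistinguishable from the joint map, which is what
transfers the sharper of the two source textures into the fusion.

Conventions (configurable where noted):

* Laplacian kernel: 3x3 4-neighbour ``[[0,1,0],[1,-4,1],[0,1,0]]`` by
  default; the 8-neighbour variant is available via ``kernel="8"``.
* Boundary handling: edge-mirrored (symmetric) padding, so the output has
  the input's size and the image border does not register as an artificial
  edge — important for functional images that are mostly black background.
* Maps are fed to the discriminator unnormalized; Laplacian responses of
  ``[0, 1]`` images are already O(1).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .types import check_finite, check_same_shape

__all__ = ["laplacian_kernel", "laplacian", "fused_gradient", "joint_gradient"]

_KERNELS = {
    "4": np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]),
    "8": np.array([[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]]),
}


def laplacian_kernel(kernel: str = "4") -> np.ndarray:
    """Return the discrete Laplace kernel (``"4"`` or ``"8"`` neighbour)."""
    try:
        return _KERNELS[str(kernel)].copy()
    except KeyError:
        raise InvalidInputError(f"unknown Laplacian kernel {kernel!r}; use '4' or '8'")


def laplacian(img: np.ndarray, kernel: str = "4") -> np.ndarray:
    """Signed discrete Laplacian with edge-mirrored boundaries.

    The response is zero on constant and affine-ramp regions and annihilates
    smooth background, so it isolates texture and edges.
    """
    arr = check_finite(img, name="image")
    if arr.ndim != 2:
        raise InvalidInputError(f"expected 2-D image, got shape {arr.shape}")
    k = laplacian_kernel(kernel)
    if arr.shape[0] < k.shape[0] or arr.shape[1] < k.shape[1]:
        raise InvalidInputError(
            f"image {arr.shape} smaller than Laplacian kernel {k.shape}"
        )
    # scipy's "reflect" mode mirrors including the edge sample (symmetric).
    return ndimage.convolve(arr, k, mode="reflect")


def fused_gradient(fused: np.ndarray, kernel: str = "4") -> np.ndarray:
    """Absolute Laplacian of a fused image — the discriminator's "false" data."""
    return np.abs(laplacian(fused, kernel))


def joint_gradient(m: np.ndarray, i: np.ndarray, kernel: str = "4") -> np.ndarray:
    """Joint gradient map — the discriminator's "real" data.

    Pixelwise maximum of the absolute Laplacians of the two co-registered
    inputs: at every pixel it records the stronger of the two source
    textures.  Symmetric in its arguments and elementwise >= either
    individual absolute Laplacian.
    """
    m = check_finite(m, name="m")
    i = check_finite(i, name="i")
    check_same_shape(m, i, names="joint_gradient inputs")
    return np.maximum(np.abs(laplacian(m, kernel)), np.abs(laplacian(i, kernel)))
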