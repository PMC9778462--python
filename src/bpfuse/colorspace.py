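"""RGB <-> YCbCr conversion around the luminance-channel fusion core.

Functional modalities (PET/SPECT) arrive as pseudo-color RGB images.  Only
their luminance carries the structure the fusion network operates on, so the
pipeline is: split off Y, fuse Y with the structural (MRI) image, then
recombine the fused Y with the untouched Cb/Cr chroma planes and transform
back to RGB.  Chroma — and therefore the functional color coding — passes
through the fusion unchanged.

The conversion uses the full-range BT.601 primaries

    Y  =  0.299 R + 0.587 G + 0.114 B
    Cb = (B - Y) / 1.772 + 1/2
    Cr = (R - Y) / 1.402 + 1/2

so that all three planes live in ``[0, 1]`` (chroma is zero-centred and
offset by +0.5).  Out-of-gamut values produced by the inverse transform are
clipped to ``[0, 1]``; in-gamut pixels round-trip losslessly to float
precision.  Single-channel CT images never pass through this module — they
are fused directly as grayscale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .types import as_color_image, as_gray_image, check_same_shape

__all__ = ["YCbCrPlanes", "rgb_to_ycbcr", "ycbcr_to_rgb", "recombine"]

# Full-range BT.601 forward matrix (rows: Y, Cb, Cr; columns: R, G, B).
_KR, _KG, _KB = 0.299, 0.587, 0.114
_FWD = np.array(
    [
        [_KR, _KG, _KB],
        [-_KR / 1.772, -_KG / 1.772, (1.0 - _KB) / 1.772],
        [(1.0 - _KR) / 1.402, -_KG / 1.402, -_KB / 1.402],
    ]
)
_INV = np.linalg.inv(_FWD)


@dataclass(frozen=True)
class YCbCrPlanes:
    """Luminance and chroma planes of one color image, each in ``[0, 1]``."""

    y: np.ndarray
    cb: np.ndarray
    cr: np.ndarray

    def __post_init__(self):
        check_same_shape(self.y, self.cb, self.cr, names="YCbCr planes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape


def rgb_to_ycbcr(img: np.ndarray) -> YCbCrPlanes:
    """Decompose an RGB image into luminance and offset chroma planes.

    Parameters
    ----------
    img : ndarray, shape (H, W, 3)
        RGB intensities in ``[0, 1]``.

    Returns
    -------
    YCbCrPlanes
        ``y`` in ``[0, 1]``; ``cb``/``cr`` zero-centred chroma stored with a
        +0.5 offset so a neutral (gray) pixel has ``cb = cr = 0.5``.
    """
    arr = as_color_image(img, name="rgb image", min_size=8)
    ycc = arr @ _FWD.T
    ycc[..., 1:] += 0.5
    return YCbCrPlanes(y=ycc[..., 0], cb=ycc[..., 1], cr=ycc[..., 2])


def ycbcr_to_rgb(planes: YCbCrPlanes) -> np.ndarray:
    """Inverse transform; output clipped to ``[0, 1]``.

    Exact inverse of :func:`rgb_to_ycbcr` up to clipping and float
    tolerance.
    """
    if not isinstance(planes, YCbCrPlanes):
        raise InvalidInputError("ycbcr_to_rgb expects a YCbCrPlanes instance")
    ycc = np.stack([planes.y, planes.cb - 0.5, planes.cr - 0.5], axis=-1)
    if not np.all(np.isfinite(ycc)):
        raise InvalidInputError("YCbCr planes contain non-finite values")
    rgb = ycc @ _INV.T
    return np.clip(rgb, 0.0, 1.0)


def recombine(fused_y: np.ndarray, source: YCbCrPlanes) -> np.ndarray:
    """Replace the luminance of ``source`` with ``fused_y`` and return RGB.

    This is the chroma-passthrough step: the Cb/Cr planes of ``source`` are
    used verbatim, so re-decomposing the output recovers them within float
    tolerance wherever the result stays in gamut.
    """
    y = as_gray_image(fused_y, name="fused luminance")
    if y.shape != source.shape:
        raise InvalidInputError(
            f"fused luminance shape {y.shape} does not match source planes "
            f"{source.shape}"
        )
    return ycbcr_to_rgb(YCbCrPlanes(y=y, cb=source.cb, cr=source.cr))
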