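"""PNG/TIFF image I/O with [0, 1] normalization.

8- and 16-bit integer images load as floats in [0, 1] (divided by the
dtype maximum); float TIFFs load as-is.  Grayscale files come back as 2-D
arrays, color files as H x W x 3 (alpha, if present, is dropped).  Signed
or unbounded gradient maps are written as 32-bit float TIFF.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError

__all__ = ["load_image", "save_image", "save_gradient_map", "load_gradient_map"]

_SUPPORTED = {".png", ".tif", ".tiff"}


def load_image(path, *, with_depth: bool = False):
    """Load a PNG/TIFF as float64 in [0, 1].

    With ``with_depth=True`` also return the source bit depth (8, 16, or 0
    for float input) for round-trip saving.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise InvalidInputError(f"unsupported image format: {path.suffix!r}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # corrupt / unreadable file
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc
    if raw.dtype == np.uint8:
        arr, depth = raw.astype(np.float64) / 255.0, 8
    elif raw.dtype == np.uint16:
        arr, depth = raw.astype(np.float64) / 65535.0, 16
    elif np.issubdtype(raw.dtype, np.floating):
        arr, depth = raw.astype(np.float64), 0
    else:
        raise InvalidInputError(f"unsupported pixel dtype {raw.dtype} in {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        elif arr.shape[2] != 3:
            raise InvalidInputError(
                f"{path}: expected 1, 3 or 4 channels, got {arr.shape[2]}"
            )
    elif arr.ndim != 2:
        raise InvalidInputError(f"{path}: unsupported image rank {arr.ndim}")
    return (arr, depth) if with_depth else arr


def save_image(path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Save a [0, 1] image as 8- or 16-bit PNG/TIFF."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise InvalidInputError(f"unsupported image format: {path.suffix!r}")
    arr = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("image contains non-finite values")
    arr = np.clip(arr, 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(arr * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(arr * 65535.0).astype(np.uint16)
    else:
        raise InvalidInputError(f"unsupported bit depth {bit_depth}")
    iio.imwrite(path, data)


def save_gradient_map(path, grad: np.ndarray) -> None:
    """Write a signed/unbounded gradient map as 32-bit float TIFF."""
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        raise InvalidInputError("gradient maps are written as TIFF")
    iio.imwrite(path, np.asarray(grad, dtype=np.float32))


def load_gradient_map(path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.float64)
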