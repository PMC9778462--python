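"""Lightweight validation helpers for the in-memory image types.

Images are plain ``numpy`` arrays throughout the package:

* ``GrayImage`` — 2-D ``float`` array with intensities in ``[0, 1]``.
* ``ColorImage`` — ``H x W x 3`` ``float`` array in ``[0, 1]``.
* ``GradientMap`` — 2-D ``float`` array, unbounded (signed Laplacian
  responses) or non-negative (absolute / joint maps).

The helpers below centralise the precondition checks so every public
operation raises the same :class:`~bpfuse.errors.InvalidInputError` with a
useful message.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "as_gray_image",
    "as_color_image",
    "check_same_shape",
    "check_finite",
]


def as_gray_image(img, *, name: str = "image", min_size: int = 1) -> np.ndarray:
    """Validate and return a 2-D intensity image as ``float64``.

    Raises
    ------
    InvalidInputError
        If the array is not 2-D, contains non-finite values, has values
        outside ``[0, 1]``, or is smaller than ``min_size`` on a side.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"{name}: expected a 2-D array, got shape {arr.shape}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise InvalidInputError(
            f"{name}: image of shape {arr.shape} is smaller than the required "
            f"minimum {min_size}x{min_size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name}: contains non-finite values")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise InvalidInputError(
            f"{name}: intensities must lie in [0, 1]; got range "
            f"[{arr.min():.4g}, {arr.max():.4g}]"
        )
    return np.clip(arr, 0.0, 1.0)


def as_color_image(img, *, name: str = "image", min_size: int = 1) -> np.ndarray:
    """Validate and return an ``H x W x 3`` color image as ``float64``."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(
            f"{name}: expected an HxWx3 array, got shape {arr.shape}"
        )
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise InvalidInputError(
            f"{name}: image of shape {arr.shape[:2]} is smaller than the "
            f"required minimum {min_size}x{min_size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name}: contains non-finite values")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise InvalidInputError(
            f"{name}: intensities must lie in [0, 1]; got range "
            f"[{arr.min():.4g}, {arr.max():.4g}]"
        )
    return np.clip(arr, 0.0, 1.0)


def check_same_shape(*arrays: np.ndarray, names: str = "inputs") -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise InvalidInputError(f"{names}: shapes differ: {sorted(shapes)}")


def check_finite(arr: np.ndarray, *, name: str = "array") -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name}: contains non-finite values")
    return arr
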