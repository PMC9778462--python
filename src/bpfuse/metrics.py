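"""Fusion-quality metrics: AG, EI, Q_abf, Q_cv.

* ``AG`` (average gradient) — mean forward-difference gradient magnitude,
  a sharpness proxy.  Implemented exactly as the source formula prints it,
  with the 1/4 factor *inside* the square root:

      AG = 1/((H-1)(W-1)) * sum sqrt( ((dg/dh)^2 + (dg/dw)^2) / 4 )

  The more common convention divides by 2 instead of 4; that variant is
  available via ``variant="half"`` and is exactly ``sqrt(2)`` times larger.
* ``EI`` (edge intensity) — mean Sobel gradient magnitude.
* ``Q_abf`` — saliency-weighted windowed quality: in each window the
  Wang–Bovik universal image quality index Q0 of (A, F) and (B, F) is mixed
  with weight ``lambda(w) = s(A|w) / (s(A|w) + s(B|w))`` where ``s`` is the
  window variance; the result is averaged over windows.  Lies in [-1, 1];
  1 at perfect self-fusion.
* ``Q_cv`` — human-visual-system-weighted regional MSE: difference images
  ``A - F`` and ``B - F`` are band-filtered with a Gaussian (sigma 1.5 by
  default), their per-window mean squared errors are weighted by windowed
  edge saliency (mean Sobel magnitude), and the weighted mean is returned.
  Lower is better; 0 at perfect self-fusion.

Windows tile the image including final partial windows.  Defaults: 8x8
stride 8 for Q_abf, 16x16 stride 16 for Q_cv.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .types import check_finite, check_same_shape

__all__ = [
    "WindowSpec", "MetricReport",
    "average_gradient", "edge_intensity", "q_abf", "q_cv", "metric_report",
]

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T


@dataclass(frozen=True)
class WindowSpec:
    """Square analysis window tiling for the windowed metrics."""

    size: int = 8
    stride: int = 8

    def __post_init__(self):
        if self.size < 2:
            raise InvalidInputError("window size must be >= 2")
        if self.stride < 1:
            raise InvalidInputError("window stride must be >= 1")

    def windows(self, h: int, w: int):
        """Yield (row-slice, col-slice) covering the full image domain."""
        for r0 in range(0, h, self.stride):
            for c0 in range(0, w, self.stride):
                yield (slice(r0, min(r0 + self.size, h)),
                       slice(c0, min(c0 + self.size, w)))


@dataclass(frozen=True)
class MetricReport:
    """The four fusion-quality numbers for one (A, B, F) triple."""

    ag: float
    ei: float
    q_abf: float
    q_cv: float

    def as_dict(self) -> dict[str, float]:
        return {"ag": self.ag, "ei": self.ei,
                "q_abf": self.q_abf, "q_cv": self.q_cv}


def _gray(img, name, min_h=1, min_w=1) -> np.ndarray:
    arr = check_finite(img, name=name)
    if arr.ndim != 2:
        raise InvalidInputError(f"{name}: expected 2-D image, got {arr.shape}")
    if arr.shape[0] < min_h or arr.shape[1] < min_w:
        raise InvalidInputError(
            f"{name}: image {arr.shape} too small (need >= {min_h}x{min_w})"
        )
    return arr


def average_gradient(img: np.ndarray, variant: str = "quarter") -> float:
    """Mean forward-difference gradient magnitude over the (H-1)x(W-1) grid."""
    g = _gray(img, "image", 2, 2)
    dh = g[1:, :-1] - g[:-1, :-1]
    dw = g[:-1, 1:] - g[:-1, :-1]
    if variant == "quarter":          # as the formula prints it
        mag = np.sqrt((dh * dh + dw * dw) / 4.0)
    elif variant == "half":           # the common literature convention
        mag = np.sqrt((dh * dh + dw * dw) / 2.0)
    else:
        raise InvalidInputError(f"unknown AG variant {variant!r}")
    return float(mag.mean())


def edge_intensity(img: np.ndarray) -> float:
    """Mean Sobel gradient magnitude with mirrored boundaries."""
    g = _gray(img, "image", 3, 3)
    sx = ndimage.convolve(g, SOBEL_X, mode="reflect")
    sy = ndimage.convolve(g, SOBEL_Y, mode="reflect")
    return float(np.sqrt(sx * sx + sy * sy).mean())


def _q0(x: np.ndarray, y: np.ndarray) -> float:
    """Wang–Bovik universal image quality index of two equal windows."""
    mx, my = x.mean(), y.mean()
    vx = x.var()
    vy = y.var()
    cxy = ((x - mx) * (y - my)).mean()
    d1 = vx + vy
    d2 = mx * mx + my * my
    if d1 > 0 and d2 > 0:
        return float(4.0 * cxy * mx * my / (d1 * d2))
    if d1 == 0 and d2 > 0:            # flat windows: luminance term only
        return float(2.0 * mx * my / d2)
    if d1 > 0:                        # zero-mean windows: structure term only
        return float(2.0 * cxy / d1)
    return 1.0                        # both flat and zero: identical windows


def q_abf(a: np.ndarray, b: np.ndarray, f: np.ndarray,
          win: WindowSpec = WindowSpec(8, 8)) -> float:
    """Saliency-weighted windowed quality of the fusion F of sources A, B."""
    a = _gray(a, "a")
    b = _gray(b, "b")
    f = _gray(f, "f")
    check_same_shape(a, b, f, names="q_abf inputs")
    total = 0.0
    count = 0
    for rs, cs in win.windows(*a.shape):
        aw, bw, fw = a[rs, cs], b[rs, cs], f[rs, cs]
        sa, sb = aw.var(), bw.var()
        lam = sa / (sa + sb) if sa + sb > 0 else 0.5
        total += lam * _q0(aw, fw) + (1.0 - lam) * _q0(bw, fw)
        count += 1
    return total / count


def _sobel_magnitude(img: np.ndarray) -> np.ndarray:
    sx = ndimage.convolve(img, SOBEL_X, mode="reflect")
    sy = ndimage.convolve(img, SOBEL_Y, mode="reflect")
    return np.sqrt(sx * sx + sy * sy)


def q_cv(a: np.ndarray, b: np.ndarray, f: np.ndarray,
         win: WindowSpec = WindowSpec(16, 16), *,
         sigma: float = 1.5, saliency_power: float = 1.0) -> float:
    """Edge-saliency-weighted regional MSE of band-filtered differences.

    Lower is better; exactly 0 when ``f`` equals both sources.
    """
    a = _gray(a, "a", 3, 3)
    b = _gray(b, "b", 3, 3)
    f = _gray(f, "f", 3, 3)
    check_same_shape(a, b, f, names="q_cv inputs")
    da = ndimage.gaussian_filter(a - f, sigma, mode="reflect")
    db = ndimage.gaussian_filter(b - f, sigma, mode="reflect")
    sal_a = _sobel_magnitude(a)
    sal_b = _sobel_magnitude(b)
    num = 0.0
    den = 0.0
    for rs, cs in win.windows(*a.shape):
        la = sal_a[rs, cs].mean() ** saliency_power
        lb = sal_b[rs, cs].mean() ** saliency_power
        num += la * np.mean(da[rs, cs] ** 2) + lb * np.mean(db[rs, cs] ** 2)
        den += la + lb
    return float(num / den) if den > 0 else 0.0


def metric_report(a: np.ndarray, b: np.ndarray, f: np.ndarray, *,
                  abf_win: WindowSpec = WindowSpec(8, 8),
                  cv_win: WindowSpec = WindowSpec(16, 16)) -> MetricReport:
    """Compute all four metrics for one fusion triple (sources A, B; fused F)."""
    return MetricReport(
        ag=average_gradient(f),
        ei=edge_intensity(f),
        q_abf=q_abf(a, b, f, abf_win),
        q_cv=q_cv(a, b, f, cv_win),
    )
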