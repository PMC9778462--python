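"""Independent brute-force oracles for metrics, gradients and screening.

Everything here is written as plain per-pixel / per-window Python loops,
straight from the mathematical definitions, deliberately sharing no code
with the package implementations they are used to verify.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

LAP4 = [[0, 1, 0], [1, -4, 1], [0, 1, 0]]
SX = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
SY = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]


def conv_loop(img: np.ndarray, kernel) -> np.ndarray:
    """True 3x3 convolution (kernel flipped) with edge-mirrored padding."""
    k = np.asarray(kernel, dtype=float)
    p = np.pad(img, 1, mode="symmetric")
    h, w = img.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(3):
                for j in range(3):
                    acc += k[2 - i, 2 - j] * p[r + i, c + j]
            out[r, c] = acc
    return out


def laplacian_loop(img: np.ndarray) -> np.ndarray:
    return conv_loop(img, LAP4)


def joint_gradient_loop(m: np.ndarray, i: np.ndarray) -> np.ndarray:
    lm = np.abs(laplacian_loop(m))
    li = np.abs(laplacian_loop(i))
    out = np.zeros_like(lm)
    for r in range(lm.shape[0]):
        for c in range(lm.shape[1]):
            out[r, c] = max(lm[r, c], li[r, c])
    return out


def window_variance_loop(img: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    p = np.pad(img, half, mode="symmetric")
    h, w = img.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            vals = [p[r + i, c + j] for i in range(window) for j in range(window)]
            mu = sum(vals) / len(vals)
            out[r, c] = sum((v - mu) ** 2 for v in vals) / len(vals)
    return out


def screening_maps_loop(m: np.ndarray, i: np.ndarray, window: int):
    vm = window_variance_loop(m, window)
    vi = window_variance_loop(i, window)
    map1 = np.zeros_like(vm)
    for r in range(vm.shape[0]):
        for c in range(vm.shape[1]):
            if vm[r, c] > vi[r, c]:
                map1[r, c] = 1.0
            elif vm[r, c] == vi[r, c]:
                map1[r, c] = 0.5
    return map1, 1.0 - map1


def average_gradient_loop(img: np.ndarray) -> float:
    h, w = img.shape
    total = 0.0
    for r in range(h - 1):
        for c in range(w - 1):
            dh = img[r + 1, c] - img[r, c]
            dw = img[r, c + 1] - img[r, c]
            total += np.sqrt((dh**2 + dw**2) / 4.0)
    return total / ((h - 1) * (w - 1))


def edge_intensity_loop(img: np.ndarray) -> float:
    sx = conv_loop(img, SX)
    sy = conv_loop(img, SY)
    h, w = img.shape
    total = 0.0
    for r in range(h):
        for c in range(w):
            total += np.sqrt(sx[r, c] ** 2 + sy[r, c] ** 2)
    return total / (h * w)


def _windows(h, w, size, stride):
    for r0 in range(0, h, stride):
        for c0 in range(0, w, stride):
            yield r0, min(r0 + size, h), c0, min(c0 + size, w)


def uiqi_loop(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    mx = sum(x.ravel()) / n
    my = sum(y.ravel()) / n
    vx = sum((v - mx) ** 2 for v in x.ravel()) / n
    vy = sum((v - my) ** 2 for v in y.ravel()) / n
    cxy = sum((a - mx) * (b - my) for a, b in zip(x.ravel(), y.ravel())) / n
    d1, d2 = vx + vy, mx * mx + my * my
    if d1 > 0 and d2 > 0:
        return 4 * cxy * mx * my / (d1 * d2)
    if d1 == 0 and d2 > 0:
        return 2 * mx * my / d2
    if d1 > 0:
        return 2 * cxy / d1
    return 1.0


def q_abf_loop(a, b, f, size=8, stride=8) -> float:
    h, w = a.shape
    total, count = 0.0, 0
    for r0, r1, c0, c1 in _windows(h, w, size, stride):
        aw, bw, fw = a[r0:r1, c0:c1], b[r0:r1, c0:c1], f[r0:r1, c0:c1]
        sa = sum((v - aw.mean()) ** 2 for v in aw.ravel()) / aw.size
        sb = sum((v - bw.mean()) ** 2 for v in bw.ravel()) / bw.size
        lam = sa / (sa + sb) if sa + sb > 0 else 0.5
        total += lam * uiqi_loop(aw, fw) + (1 - lam) * uiqi_loop(bw, fw)
        count += 1
    return total / count


def q_cv_loop(a, b, f, size=16, stride=16, sigma=1.5) -> float:
    # the Gaussian band filter is taken as given; windowing, saliency and
    # the weighted aggregation are recomputed by explicit loops
    da = ndimage.gaussian_filter(a - f, sigma, mode="reflect")
    db = ndimage.gaussian_filter(b - f, sigma, mode="reflect")
    sal_a = np.sqrt(conv_loop(a, SX) ** 2 + conv_loop(a, SY) ** 2)
    sal_b = np.sqrt(conv_loop(b, SX) ** 2 + conv_loop(b, SY) ** 2)
    num = den = 0.0
    for r0, r1, c0, c1 in _windows(*a.shape, size, stride):
        la = sum(sal_a[r0:r1, c0:c1].ravel()) / ((r1 - r0) * (c1 - c0))
        lb = sum(sal_b[r0:r1, c0:c1].ravel()) / ((r1 - r0) * (c1 - c0))
        mse_a = sum(v * v for v in da[r0:r1, c0:c1].ravel()) / ((r1 - r0) * (c1 - c0))
        mse_b = sum(v * v for v in db[r0:r1, c0:c1].ravel()) / ((r1 - r0) * (c1 - c0))
        num += la * mse_a + lb * mse_b
        den += la + lb
    return num / den if den > 0 else 0.0


def pixel_loss_loop(fused, m, i, map1, map2) -> float:
    h, w = fused.shape
    total = 0.0
    for r in range(h):
        for c in range(w):
            total += (map1[r, c] * (fused[r, c] - m[r, c]) ** 2
                      + map2[r, c] * (fused[r, c] - i[r, c]) ** 2)
    return total / (h * w)


def gradient_loss_loop(fused, m, y, map1, map2) -> float:
    lf = laplacian_loop(fused)
    lm = laplacian_loop(m)
    ly = laplacian_loop(y)
    return pixel_loss_loop(lf, lm, ly, map1, map2) * 1.0
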