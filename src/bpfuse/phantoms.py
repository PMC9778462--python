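"""Synthetic co-registered multi-modal phantom pairs.

The fusion method assumes two statistically very different inputs:

* a *structural* image (MRI/CT-like): overlapping elliptical organs with
  sharp boundaries, ring structures, and fine sinusoidal texture — high
  local gradient everywhere inside the anatomy;
* a *functional* image (PET/SPECT-like): a handful of smooth Gaussian
  activity blobs rendered through a clinical-style pseudo-color ramp
  (black -> blue -> green -> yellow -> red) on a predominantly *exactly
  black* background — the property the back-project block is designed to
  cope with.

Pairs generated from one :class:`PhantomSpec` are co-registered by
construction: both modalities are derived from the same random geometry
(the functional blobs are centred inside the structural shapes), not by
post-hoc warping.  Everything is deterministic per seed, so a dataset can
be regenerated byte-for-byte.

Defaults follow the data regime the method was designed for: 256 x 256
images, ~70% black background in the functional modality, light noise on
the structural modality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = ["PhantomSpec", "make_structural", "make_functional",
           "make_pair", "make_dataset", "pseudocolor_ramp"]


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (256, 256)
    n_structures: int = 5        # elliptical organs / rings
    texture_freq: float = 0.12   # cycles per pixel of the sinusoidal texture
    n_blobs: int = 3             # functional activity foci
    blob_sigma: float = 12.0     # Gaussian width of a focus, in pixels
    background_fraction: float = 0.7
    noise_sd: float = 0.01       # additive Gaussian noise on the structural image
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if h < 16 or w < 16:
            raise InvalidInputError("phantom size must be at least 16x16")
        if not 0 <= self.background_fraction < 1:
            raise InvalidInputError("background_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if self.n_structures < 0 or self.n_blobs < 0:
            raise InvalidInputError("structure/blob counts must be >= 0")
        if self.blob_sigma <= 0:
            raise InvalidInputError("blob_sigma must be positive")


# three independent RNG streams per seed so each modality is reproducible
# on its own while still sharing the geometry
def _rngs(spec: PhantomSpec):
    root = np.random.SeedSequence(spec.seed)
    geo, tex, fun = root.spawn(3)
    return (np.random.default_rng(geo), np.random.default_rng(tex),
            np.random.default_rng(fun))


def _geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Sample the shared anatomy: ellipse parameters for each structure."""
    h, w = spec.size
    shapes = []
    for _ in range(spec.n_structures):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        ry = rng.uniform(0.10 * h, 0.30 * h)
        rx = rng.uniform(0.10 * w, 0.30 * w)
        theta = rng.uniform(0, np.pi)
        level = rng.uniform(0.35, 0.9)
        ring = rng.random() < 0.5
        shapes.append((cy, cx, ry, rx, theta, level, ring))
    return shapes


def _ellipse_field(spec: PhantomSpec, shapes):
    """Normalized squared elliptical distance per shape, plus union mask."""
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    fields = []
    for cy, cx, ry, rx, theta, _level, _ring in shapes:
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        fields.append((u / ry) ** 2 + (v / rx) ** 2)
    return fields


def make_structural(spec: PhantomSpec) -> np.ndarray:
    """Render the sharp, textured structural (MRI/CT-like) phantom."""
    geo_rng, tex_rng, _ = _rngs(spec)
    h, w = spec.size
    shapes = _geometry(spec, geo_rng)
    img = np.zeros((h, w))
    fields = _ellipse_field(spec, shapes)
    for field, (_, _, _, _, _, level, ring) in zip(fields, shapes):
        inside = field <= 1.0
        if ring:  # bright rim with a darker interior, like a skull/ventricle
            rim = (field <= 1.0) & (field >= 0.64)
            img[inside] = np.maximum(img[inside], 0.45 * level)
            img[rim] = np.maximum(img[rim], level)
        else:
            img[inside] = np.maximum(img[inside], level)
    if spec.n_structures and spec.texture_freq > 0:
        # oriented sinusoidal texture confined to the anatomy
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        phi = tex_rng.uniform(0, 2 * np.pi)
        ang = tex_rng.uniform(0, np.pi)
        carrier = np.sin(
            2 * np.pi * spec.texture_freq * (yy * np.cos(ang) + xx * np.sin(ang))
            + phi
        )
        img += 0.12 * carrier * (img > 0)
    if spec.noise_sd > 0:
        img += tex_rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def pseudocolor_ramp(t: np.ndarray) -> np.ndarray:
    """Piecewise-linear black->blue->green->yellow->red clinical-style ramp."""
    t = np.clip(np.asarray(t, dtype=np.float64), 0.0, 1.0)
    stops = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    colors = np.array([
        [0.0, 0.0, 0.0],   # black
        [0.0, 0.0, 1.0],   # blue
        [0.0, 1.0, 0.0],   # green
        [1.0, 1.0, 0.0],   # yellow
        [1.0, 0.0, 0.0],   # red
    ])
    out = np.empty(t.shape + (3,))
    for ch in range(3):
        out[..., ch] = np.interp(t, stops, colors[:, ch])
    return out


def make_functional(spec: PhantomSpec) -> np.ndarray:
    """Render the smooth pseudo-color functional (PET/SPECT-like) phantom.

    Blob centres are sampled inside the structural shapes of the *same*
    spec, so the pair is co-registered.  At least ``background_fraction``
    of the pixels are exactly ``(0, 0, 0)``.
    """
    geo_rng, _, fun_rng = _rngs(spec)
    h, w = spec.size
    shapes = _geometry(spec, geo_rng)   # identical to the structural geometry
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    intensity = np.zeros((h, w))
    for _ in range(spec.n_blobs):
        if shapes:
            cy, cx, ry, rx, theta, _, _ = shapes[fun_rng.integers(len(shapes))]
            by = np.clip(cy + fun_rng.normal(0, 0.3 * ry), 0, h - 1)
            bx = np.clip(cx + fun_rng.normal(0, 0.3 * rx), 0, w - 1)
        else:
            by = fun_rng.uniform(0.25 * h, 0.75 * h)
            bx = fun_rng.uniform(0.25 * w, 0.75 * w)
        amp = fun_rng.uniform(0.6, 1.0)
        intensity += amp * np.exp(
            -((yy - by) ** 2 + (xx - bx) ** 2) / (2 * spec.blob_sigma**2)
        )
    if intensity.max() > 0:
        intensity /= intensity.max()
    # zero out the dimmest pixels so the exact-black fraction is guaranteed
    cutoff = max(np.quantile(intensity, spec.background_fraction), 1e-3)
    intensity = np.where(intensity > cutoff, intensity, 0.0)
    return pseudocolor_ramp(intensity)


def make_pair(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """One co-registered (structural, functional) pair."""
    return make_structural(spec), make_functional(spec)


def make_dataset(spec: PhantomSpec, n: int, out_dir) -> Path:
    """Write ``n`` pairs as 8-bit PNGs plus a TSV manifest; returns its path.

    Pair ``k`` uses ``spec.seed + k`` so the dataset is reproducible and
    every pair is distinct.
    """
    from . import io as bio  # local import: io pulls in imageio

    if n < 1:
        raise InvalidInputError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["structural\tfunctional\tseed"]
    for k in range(n):
        pair_spec = replace(spec, seed=spec.seed + k)
        structural, functional = make_pair(pair_spec)
        spath = out / f"pair{k:04d}_structural.png"
        fpath = out / f"pair{k:04d}_functional.png"
        bio.save_image(spath, structural)
        bio.save_image(fpath, functional)
        rows.append(f"{spath.name}\t{fpath.name}\t{pair_spec.seed}")
    manifest = out / "manifest.tsv"
    header = (
        f"# phantom dataset: n={n} size={spec.size[0]}x{spec.size[1]} "
        f"seed={spec.seed} background_fraction={spec.background_fraction}\n"
    )
    manifest.write_text(header + "\n".join(rows) + "\n")
    return manifest
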