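"""Seeded generator of three-class leaf-like test images.

The three classes mimic the structure of bean leaf disease photographs at
the level of spatial-frequency content, not photorealism:

``healthy``
    a smooth green leaf on a plain background with only low-frequency
    shading (a few cosine modes at 1-3 cycles per image);
``bean_rust``
    the same base plus many small dark pustule-like speckles (Gaussian
    bumps of sigma ~1 px), concentrating energy in the high-frequency band
    of a 16 x 16 block spectrum;
``angular_leaf_spot``
    the same base plus a handful of larger soft-edged brown blotches
    (radius ~7-12 px), i.e. mid-frequency texture.

The base leaf is drawn from a random stream that depends only on the seed,
never on the class, so a lesion class generated with density 0 is pixel-
identical to its healthy counterpart at the same seed.  Lesion geometry is
chosen so a 16-pixel block straddles several lesion periods, which makes
the block-wise enhancement effect measurable inside single blocks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enhancer import pad_to_block_multiple
from .io import CLASS_NAMES, DatasetManifest, save_image
from .transform import forward_dct

__all__ = [
    "SyntheticSpec",
    "generate_leaf_image",
    "generate_arrays",
    "generate_dataset",
    "high_band_energy",
    "band_energy_ratio",
]

# lesion texture constants (pixels); speckles live above, blotches below,
# the k1 + k2 = B diagonal of a B = 16 block spectrum
SPECKLE_SIGMA_RANGE = (0.7, 1.3)
SPECKLE_BASE_COUNT = 800  # at density 1.0 on a 224-pixel side
BLOTCH_RADIUS_RANGE = (7.0, 12.0)
BLOTCH_BASE_COUNT = 16
LESION_COLOR = np.array([95.0, 68.0, 38.0])  # shared brown so colour is a weak cue

_BACKGROUND = np.array([185.0, 178.0, 160.0])
_LEAF_GREEN = np.array([70.0, 118.0, 58.0])


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic leaf image."""

    class_name: str
    side: int = 224
    lesion_density: float = 0.5
    base_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"unknown class {self.class_name!r}; expected one of {CLASS_NAMES}"
            )
        if self.side < 32:
            raise ValueError("side must be >= 32")
        if not 0.0 <= self.lesion_density <= 1.0:
            raise ValueError("lesion_density must lie in [0, 1]")


def _leaf_base(side: int, jitter: float, rng: np.random.Generator):
    """Smooth leaf-on-background base image and its soft leaf mask."""
    s = float(side)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    cy = s / 2 + rng.uniform(-0.03, 0.03) * s
    cx = s / 2 + rng.uniform(-0.03, 0.03) * s
    a = 0.40 * s * (1 + rng.uniform(-jitter, jitter))
    b = 0.28 * s * (1 + rng.uniform(-jitter, jitter))
    theta = rng.uniform(-0.6, 0.6)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    mask = 1.0 / (1.0 + np.exp(-(1.0 - rho) * (a / 2.0)))  # ~2 px soft edge

    green = _LEAF_GREEN * (1 + rng.uniform(-jitter, jitter, size=3))
    shading = np.zeros((side, side))
    for _ in range(2):  # low-frequency shading: 1-3 cycles per image
        fx, fy = rng.integers(0, 3, size=2)
        amp = rng.uniform(4.0, 9.0)
        phase = rng.uniform(0, 2 * np.pi)
        shading += amp * np.cos(2 * np.pi * (fx * xx + fy * yy) / s + phase)
    leaf = green[None, None, :] + shading[..., None]
    img = _BACKGROUND[None, None, :] * (1 - mask[..., None]) + leaf * mask[..., None]
    geom = (cx, cy, a, b, theta)
    return img, mask, geom


def _points_in_leaf(n: int, geom, rng: np.random.Generator) -> np.ndarray:
    cx, cy, a, b, theta = geom
    u = np.sqrt(rng.uniform(0, 1, size=n)) * 0.92  # stay inside the soft edge
    phi = rng.uniform(0, 2 * np.pi, size=n)
    ex, ey = u * np.cos(phi) * a, u * np.sin(phi) * b
    px = cx + ex * np.cos(theta) - ey * np.sin(theta)
    py = cy + ex * np.sin(theta) + ey * np.cos(theta)
    return np.stack([px, py], axis=1)


def _add_bumps(weight, centers, sizes, amps, profile):
    """Accumulate radial lesion bumps into the [0, 1] weight field."""
    side = weight.shape[0]
    for (px, py), size, amp in zip(centers, sizes, amps):
        r_max = profile["support"](size)
        x0, x1 = max(int(px - r_max), 0), min(int(px + r_max) + 1, side)
        y0, y1 = max(int(py - r_max), 0), min(int(py + r_max) + 1, side)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        r = np.hypot(xx - px, yy - py)
        weight[y0:y1, x0:x1] += amp * profile["shape"](r, size)
    np.clip(weight, 0.0, 1.0, out=weight)


_SPECKLE = {
    "support": lambda sigma: 4.0 * sigma,
    "shape": lambda r, sigma: np.exp(-(r**2) / (2.0 * sigma**2)),
}
_BLOTCH = {
    "support": lambda radius: radius + 6.0,
    "shape": lambda r, radius: 1.0 / (1.0 + np.exp((r - radius) / 1.5)),
}


def generate_leaf_image(spec: SyntheticSpec) -> tuple[np.ndarray, str]:
    """Render one image; deterministic under ``spec.seed``.

    Returns ``(image, label)`` with the image as an H x W x 3 float array in
    [0, 255].
    """
    base_rng = np.random.default_rng([spec.seed, 17])
    lesion_rng = np.random.default_rng([spec.seed, 23])
    img, mask, geom = _leaf_base(spec.side, spec.base_jitter, base_rng)

    scale = (spec.side / 224.0) ** 2
    weight = np.zeros((spec.side, spec.side))
    if spec.class_name == "bean_rust":
        n = int(round(SPECKLE_BASE_COUNT * spec.lesion_density * scale))
        centers = _points_in_leaf(n, geom, lesion_rng)
        sizes = lesion_rng.uniform(*SPECKLE_SIGMA_RANGE, size=n)
        amps = lesion_rng.uniform(0.6, 0.95, size=n)
        _add_bumps(weight, centers, sizes, amps, _SPECKLE)
    elif spec.class_name == "angular_leaf_spot":
        n = int(round(BLOTCH_BASE_COUNT * spec.lesion_density * scale))
        centers = _points_in_leaf(n, geom, lesion_rng)
        sizes = lesion_rng.uniform(*BLOTCH_RADIUS_RANGE, size=n)
        amps = lesion_rng.uniform(0.5, 0.85, size=n)
        _add_bumps(weight, centers, sizes, amps, _BLOTCH)

    if weight.any():
        w = (weight * mask)[..., None]
        img = img + w * (LESION_COLOR[None, None, :] - img)
    return np.clip(img, 0.0, 255.0), spec.class_name


def generate_arrays(
    n_per_class: int, side: int = 224, seed: int = 0, lesion_density: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """In-memory balanced dataset: (X, y) with X of shape (3n, side, side, 3)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    imgs, labels = [], []
    for ci, cls in enumerate(CLASS_NAMES):
        for i in range(n_per_class):
            img_seed = int(np.random.default_rng([seed, ci, i]).integers(0, 2**31 - 1))
            spec = SyntheticSpec(
                class_name=cls, side=side, lesion_density=lesion_density, seed=img_seed
            )
            img, label = generate_leaf_image(spec)
            imgs.append(img.astype(np.float32))
            labels.append(label)
    return np.stack(imgs), np.asarray(labels)


def generate_dataset(
    n_per_class: int,
    side: int = 224,
    seed: int = 0,
    out_dir: str | os.PathLike = "synthetic_leaves",
    lesion_density: float = 0.5,
) -> DatasetManifest:
    """Write a balanced directory-per-class PNG dataset; returns its manifest."""
    X, y = generate_arrays(n_per_class, side=side, seed=seed, lesion_density=lesion_density)
    out = Path(out_dir)
    paths, labels = [], []
    counters = {c: 0 for c in CLASS_NAMES}
    for img, cls in zip(X, y):
        cdir = out / cls
        cdir.mkdir(parents=True, exist_ok=True)
        path = cdir / f"{cls}_{counters[cls]:04d}.png"
        save_image(img, path)
        paths.append(str(path))
        labels.append(cls)
        counters[cls] += 1
    order = sorted(range(len(paths)), key=lambda i: (CLASS_NAMES.index(labels[i]), paths[i]))
    return DatasetManifest(
        paths=tuple(paths[i] for i in order), labels=tuple(labels[i] for i in order)
    )


def _block_spectra(plane: np.ndarray, block_size: int) -> np.ndarray:
    padded, _ = pad_to_block_multiple(plane, block_size)
    b = block_size
    nh, nw = padded.shape[0] // b, padded.shape[1] // b
    blocks = padded.reshape(nh, b, nw, b).transpose(0, 2, 1, 3).reshape(-1, b, b)
    return forward_dct(forward_dct(blocks, axis=-1), axis=-2)


def high_band_energy(img: np.ndarray, block_size: int = 16) -> float:
    """Mean per-block energy in coefficients with k1 + k2 > block_size."""
    return band_energy_ratio(img, block_size, normalized=False)


def band_energy_ratio(
    img: np.ndarray,
    block_size: int = 16,
    lo: int | None = None,
    normalized: bool = True,
) -> float:
    """Energy in the band k1 + k2 > lo of the block spectra.

    ``lo`` defaults to ``block_size`` (the high-frequency half of the
    spectrum).  With ``normalized=True`` the band energy is divided by the
    total spectral energy, giving the fraction of energy in the band.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if lo is None:
        lo = block_size
    k = np.arange(block_size)
    band = (k[:, None] + k[None, :]) > lo
    band_total, total = 0.0, 0.0
    for c in range(img.shape[2]):
        spec = _block_spectra(img[..., c], block_size)
        energy = spec**2
        band_total += float(energy[:, band].sum())
        total += float(energy.sum())
    n_blocks = img.shape[2] * _block_spectra(img[..., 0], block_size).shape[0]
    if not normalized:
        return band_total / n_blocks
    return band_total / total if total > 0 else 0.0
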