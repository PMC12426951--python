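"""Image reading/writing, resizing, and dataset manifests.

Datasets follow the usual directory-per-class layout with the three bean
leaf classes: ``healthy``, ``angular_leaf_spot`` and ``bean_rust``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "DatasetManifest",
    "load_image",
    "save_image",
    "resize_to",
    "scan_dataset",
]

CLASS_NAMES: tuple[str, ...] = ("healthy", "angular_leaf_spot", "bean_rust")

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class DatasetManifest:
    """An ordered collection of (image path, class label) records."""

    paths: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.paths) != len(self.labels):
            raise ValueError("paths and labels must have equal length")
        if len(set(self.paths)) != len(self.paths):
            raise ValueError("manifest paths must be unique")
        bad = set(self.labels) - set(CLASS_NAMES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.paths)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CLASS_NAMES}

    def subset(self, indices: Iterable[int]) -> "DatasetManifest":
        idx = list(indices)
        return DatasetManifest(
            paths=tuple(self.paths[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"path": self.paths, "label": self.labels})

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DatasetManifest":
        df = pd.read_csv(path, sep="\t")
        return cls(paths=tuple(df["path"]), labels=tuple(df["label"]))


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Decode a PNG/JPEG into an H x W x 3 float array in [0, 255].

    Grayscale images are promoted by channel replication; an alpha channel
    is dropped.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode image {os.fspath(path)!r}: {exc}") from exc
    return arr


def save_image(img: np.ndarray, path: str | os.PathLike, jpeg_quality: int = 95) -> None:
    """Write an image as 8-bit PNG or JPEG (clipping and rounding half-to-even).

    PNG is preferred for enhanced outputs: JPEG recompression smooths exactly
    the high frequencies the enhancement amplifies.
    """
    img = np.asarray(img, dtype=np.float64)
    data = np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)
    im = Image.fromarray(data)
    path = os.fspath(path)
    if Path(path).suffix.lower() in (".jpg", ".jpeg"):
        im.save(path, quality=jpeg_quality)
    else:
        im.save(path)


def resize_to(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinearly resize an H x W x 3 image to side x side (aspect not kept)."""
    if side < 1:
        raise ValueError("target side must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[:2] == (side, side):
        return img.copy()
    planes = [
        np.asarray(
            Image.fromarray(img[..., c].astype(np.float32), mode="F").resize(
                (side, side), resample=Image.BILINEAR
            ),
            dtype=np.float64,
        )
        for c in range(3)
    ]
    return np.stack(planes, axis=-1)


def scan_dataset(root: str | os.PathLike) -> DatasetManifest:
    """Build a manifest from a directory-per-class tree.

    Ordering is deterministic: classes in canonical order, files sorted by
    name within each class.  Subdirectories not named after a known class
    raise a configuration error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    subdirs = sorted(p.name for p in root.iterdir() if p.is_dir())
    unknown = set(subdirs) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(
            f"unknown class directories {sorted(unknown)}; expected subset of {CLASS_NAMES}"
        )
    paths: list[str] = []
    labels: list[str] = []
    for cls in CLASS_NAMES:
        cdir = root / cls
        if not cdir.is_dir():
            continue
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() in _IMAGE_EXTENSIONS:
                paths.append(str(f))
                labels.append(cls)
    if not paths:
        raise ValueError(f"no class directories with images found under {root}")
    return DatasetManifest(paths=tuple(paths), labels=tuple(labels))


def load_manifest_images(
    manifest: DatasetManifest, side: int | None = 224
) -> tuple[np.ndarray, np.ndarray]:
    """Load every manifest image (resized to ``side``) into one float array.

    Returns (X, y) with X of shape (n, side, side, 3) and y the string labels.
    """
    imgs = []
    for p in manifest.paths:
        img = load_image(p)
        if side is not None:
            img = resize_to(img, side)
        imgs.append(img.astype(np.float32))
    return np.stack(imgs), np.asarray(manifest.labels)
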