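"""Block-wise image enhancement with the weighted DCT pair.

Each channel of an RGB image is tiled into non-overlapping B x B blocks
(default B = 16, matching the 16 x 16 patch grid of patch-16 vision
backbones at 224 x 224 input).  Within a block the enhancement is the
separable 2D sequence: forward weighted DCT on every row, then on every
column, then the inverse weighted DCT on columns and finally rows.  In the
standard 2D-DCT domain this multiplies coefficient (k1, k2) by
g(k1) * g(k2) with g(k) = B^2/(B^2 - k^2), so blocks keep their mean while
high-frequency detail is amplified.

Extents that are not multiples of B (e.g. B = 15 on a 224-pixel side) are
reflect-padded to the next multiple, enhanced, and cropped back; reflection
avoids the step discontinuity an edge of constant fill would inject into the
block spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import transform as tc

__all__ = [
    "EnhancementConfig",
    "pad_to_block_multiple",
    "enhance_block_2d",
    "enhance_plane",
    "enhance_image",
    "BlockDCTEnhancer",
]

PaddingMode = Literal["reflect", "edge"]
ClipPolicy = Literal["clip", "passthrough"]
OutputMode = Literal["float", "uint8"]


@dataclass(frozen=True)
class EnhancementConfig:
    """Block enhancement settings.

    block_size: side B of the square transform blocks.
    padding_mode: how non-divisible extents are padded ('reflect' or 'edge').
    clip_policy: 'clip' limits output to [0, 255]; 'passthrough' keeps the
        raw enhanced values (they can leave the 8-bit range).
    output_mode: 'float' keeps real-valued planes; 'uint8' clips and rounds
        (half to even) for file output.
    """

    block_size: int = 16
    padding_mode: PaddingMode = "reflect"
    clip_policy: ClipPolicy = "passthrough"
    output_mode: OutputMode = "float"

    def __post_init__(self):
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.padding_mode not in ("reflect", "edge"):
            raise ValueError(f"unknown padding_mode {self.padding_mode!r}")
        if self.clip_policy not in ("clip", "passthrough"):
            raise ValueError(f"unknown clip_policy {self.clip_policy!r}")
        if self.output_mode not in ("float", "uint8"):
            raise ValueError(f"unknown output_mode {self.output_mode!r}")


def pad_to_block_multiple(
    plane: np.ndarray, block_size: int, mode: PaddingMode = "reflect"
) -> tuple[np.ndarray, tuple[int, int]]:
    """Pad a 2D plane so both extents are multiples of ``block_size``.

    Returns the padded plane and the original (H, W) for cropping back.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2 or plane.size == 0:
        raise ValueError("plane must be a non-empty 2D array")
    h, w = plane.shape
    pad_h = (-h) % block_size
    pad_w = (-w) % block_size
    if pad_h or pad_w:
        np_mode = "reflect" if mode == "reflect" else "edge"
        # reflect padding needs >= 2 samples along the padded axis
        if np_mode == "reflect" and (h < 2 or w < 2):
            np_mode = "edge"
        plane = np.pad(plane, ((0, pad_h), (0, pad_w)), mode=np_mode)
    return plane, (h, w)


def _enhance_blocks(blocks: np.ndarray) -> np.ndarray:
    """Separable 2D enhancement of a (..., B, B) stack of square blocks.

    Literal row/column sequence: forward rows, forward columns, inverse
    columns, inverse rows.
    """
    out = tc.forward_dre_dct(blocks, axis=-1)   # rows
    out = tc.forward_dre_dct(out, axis=-2)      # columns
    out = tc.inverse_dre_dct(out, axis=-2)      # columns back
    out = tc.inverse_dre_dct(out, axis=-1)      # rows back
    return out


def enhance_block_2d(block: np.ndarray) -> np.ndarray:
    """Enhance a single square B x B block."""
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise ValueError(f"block must be square 2D, got shape {block.shape}")
    return _enhance_blocks(block)


def enhance_plane(plane: np.ndarray, cfg: EnhancementConfig) -> np.ndarray:
    """Tile one channel into blocks, enhance each, and reassemble.

    Blocks are processed as one vectorised stack; since blocks are
    independent the traversal order is irrelevant to the output.
    """
    padded, (h, w) = pad_to_block_multiple(plane, cfg.block_size, cfg.padding_mode)
    b = cfg.block_size
    nh, nw = padded.shape[0] // b, padded.shape[1] // b
    blocks = padded.reshape(nh, b, nw, b).transpose(0, 2, 1, 3)
    enhanced = _enhance_blocks(blocks)
    out = enhanced.transpose(0, 2, 1, 3).reshape(nh * b, nw * b)
    return out[:h, :w]


def _finalize(img: np.ndarray, cfg: EnhancementConfig) -> np.ndarray:
    if cfg.clip_policy == "clip" or cfg.output_mode == "uint8":
        img = np.clip(img, 0.0, 255.0)
    if cfg.output_mode == "uint8":
        img = np.rint(img).astype(np.uint8)  # rint rounds half to even
    return img


def enhance_image(img: np.ndarray, cfg: EnhancementConfig | None = None) -> np.ndarray:
    """Enhance an H x W x 3 RGB image (channels processed independently)."""
    if cfg is None:
        cfg = EnhancementConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("degenerate (zero-sized) image")
    out = np.stack([enhance_plane(img[..., c], cfg) for c in range(3)], axis=-1)
    return _finalize(out, cfg)


class BlockDCTEnhancer(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn style transformer over stacks of RGB images.

    Parameters mirror :class:`EnhancementConfig`.  ``fit`` only validates
    parameters (the transform has nothing to learn) and records the
    per-frequency gain profile of the configured block size.

    Attributes
    ----------
    gain_profile_ : ndarray of shape (block_size,)
        Composite per-frequency gain g(k) = B^2/(B^2 - k^2) applied along
        each block axis.
    """

    def __init__(
        self,
        block_size: int = 16,
        padding_mode: PaddingMode = "reflect",
        clip_policy: ClipPolicy = "passthrough",
    ):
        self.block_size = block_size
        self.padding_mode = padding_mode
        self.clip_policy = clip_policy

    def _config(self) -> EnhancementConfig:
        return EnhancementConfig(
            block_size=self.block_size,
            padding_mode=self.padding_mode,
            clip_policy=self.clip_policy,
        )

    def fit(self, X=None, y=None):
        self._config()  # validates parameters
        self.gain_profile_ = tc.composite_gain(self.block_size)
        return self

    def transform(self, X) -> np.ndarray:
        """Enhance a single image (H, W, 3) or a stack (n, H, W, 3)."""
        if not hasattr(self, "gain_profile_"):
            self.fit()
        X = np.asarray(X, dtype=np.float64)
        cfg = self._config()
        if X.ndim == 3:
            return enhance_image(X, cfg)
        if X.ndim == 4:
            return np.stack([enhance_image(x, cfg) for x in X])
        raise ValueError(f"expected 3D or 4D input, got shape {X.shape}")
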