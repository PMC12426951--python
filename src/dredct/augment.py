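"""Training-time image augmentation.

The policy applies, in a fixed order and with randomness driven only by the
supplied seed: horizontal shift, rotation, vertical shift, horizontal flip
(probability 0.5) and a multiplicative brightness factor.  Geometric moves
are composed into a single affine map so the image is resampled once
(bilinear, nearest-edge fill — a constant fill would inject a strong
artificial edge into the block spectra).

Augmentation is meant for training folds only; validation and test images
are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationPolicy", "augment"]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Defaults: shifts 0.1 (fraction of the dimension), rotation +/-15 deg,
    horizontal flip on, brightness jitter factor in [0.8, 1.2]."""

    width_shift: float = 0.1
    height_shift: float = 0.1
    rotation_degrees: float = 15.0
    horizontal_flip: bool = True
    brightness: float = 0.2
    shift_in_pixels: bool = False  # interpret shifts as absolute pixels
    fill_mode: str = "nearest"

    def __post_init__(self):
        if not self.shift_in_pixels:
            if not (0.0 <= self.width_shift < 1.0 and 0.0 <= self.height_shift < 1.0):
                raise ValueError("fractional shifts must lie in [0, 1)")
        if not (0.0 <= self.rotation_degrees <= 180.0):
            raise ValueError("rotation_degrees must lie in [0, 180]")
        if self.brightness < 0:
            raise ValueError("brightness jitter must be non-negative")


def augment(
    img: np.ndarray,
    policy: AugmentationPolicy | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Apply one random draw of the policy to an H x W x 3 image."""
    if policy is None:
        policy = AugmentationPolicy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    h, w = img.shape[:2]

    max_dx = policy.width_shift if policy.shift_in_pixels else policy.width_shift * w
    max_dy = policy.height_shift if policy.shift_in_pixels else policy.height_shift * h
    dx = rng.uniform(-max_dx, max_dx) if max_dx > 0 else 0.0
    angle = (
        rng.uniform(-policy.rotation_degrees, policy.rotation_degrees)
        if policy.rotation_degrees > 0
        else 0.0
    )
    dy = rng.uniform(-max_dy, max_dy) if max_dy > 0 else 0.0
    do_flip = policy.horizontal_flip and rng.random() < 0.5
    factor = (
        rng.uniform(1.0 - policy.brightness, 1.0 + policy.brightness)
        if policy.brightness > 0
        else 1.0
    )

    out = img
    if dx != 0.0 or dy != 0.0 or angle != 0.0:
        # order of ops: horizontal shift, rotation about center, vertical shift
        theta = np.deg2rad(angle)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        shift_h = np.array([0.0, dx])
        shift_v = np.array([dy, 0.0])
        # output = R(input + shift_h - center) + center + shift_v
        # affine_transform maps output coords to input: inverse map
        inv = rot.T
        offset = -inv @ (center + shift_v) + center - shift_h
        out = np.stack(
            [
                ndimage.affine_transform(
                    img[..., c], inv, offset=offset, order=1, mode=policy.fill_mode
                )
                for c in range(3)
            ],
            axis=-1,
        )
    if do_flip:
        out = out[:, ::-1, :]
    if factor != 1.0:
        out = out * factor
    return np.ascontiguousarray(out)
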