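"""Deterministic image preparation for the hybrid pipeline.

Resize, per-image or dataset-level standardization, centered region-of-interest
(ROI) cropping, and non-overlapping patch extraction with per-patch reduction
to the two scalars the 2-qubit encoder consumes.

All coordinates are 0-based with half-open ranges; odd crop margins floor.
The quantum encoder operates on the [0, 1]-scaled ROI (so RY angles stay in
[0, pi] and the encoding is injective), while the standardized image feeds
the classical teacher network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "StandardizedImage",
    "standardize",
    "unstandardize",
    "center_crop",
    "extract_patches",
    "assemble_patches",
    "reduce_patch",
    "resize_image",
    "to_grayscale",
    "prepare_roi",
    "load_image_dir",
]

REDUCTIONS = ("row_mean", "first_two")


@dataclass(frozen=True)
class PreprocessConfig:
    """Geometry and reduction settings for the deterministic front end.

    ``roi_side`` must divide evenly into ``patch_side`` patches and fit inside
    the resized image; ``patch_side`` is 2 for the 2-qubit circuit.
    """

    target_side: int = 28
    roi_side: int = 14
    patch_side: int = 2
    reduction: str = "row_mean"
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.roi_side > self.target_side:
            raise ValueError("roi_side must not exceed target_side")
        if self.roi_side % self.patch_side != 0:
            raise ValueError("roi_side must be divisible by patch_side")
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"reduction must be one of {REDUCTIONS}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class StandardizedImage:
    """An image with its standardization statistics attached."""

    pixels: np.ndarray
    mu: float
    sigma: float


def standardize(image: np.ndarray, mu: float | None = None,
                sigma: float | None = None, epsilon: float = 1e-8) -> StandardizedImage:
    """Shift-and-scale normalization X' = (X - mu) / max(sigma, epsilon).

    When ``mu``/``sigma`` are omitted they default to the image's own mean and
    standard deviation.  A zero sigma (constant image) is guarded by epsilon.
    """
    image = np.asarray(image, dtype=float)
    if mu is None:
        mu = float(image.mean())
    if sigma is None:
        sigma = float(image.std())
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    denom = max(sigma, epsilon)
    return StandardizedImage((image - mu) / denom, mu, denom)


def unstandardize(std: StandardizedImage) -> np.ndarray:
    return std.pixels * std.sigma + std.mu


def center_crop(image: np.ndarray, roi_side: int) -> np.ndarray:
    """Centered ``roi_side`` x ``roi_side`` crop; odd margins floor."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if roi_side > min(h, w):
        raise ValueError(f"roi_side {roi_side} exceeds image sides {(h, w)}")
    top = (h - roi_side) // 2
    left = (w - roi_side) // 2
    return image[top:top + roi_side, left:left + roi_side]


def extract_patches(roi: np.ndarray, patch_side: int) -> np.ndarray:
    """Row-major non-overlapping tiling; shape (n_patches, patch, patch).

    Reassembling the result with :func:`assemble_patches` reproduces the ROI
    bit-exactly.
    """
    roi = np.asarray(roi)
    side = roi.shape[0]
    if roi.shape[0] != roi.shape[1]:
        raise ValueError("ROI must be square")
    if side % patch_side != 0:
        raise ValueError(f"ROI side {side} not divisible by patch side {patch_side}")
    g = side // patch_side
    tiled = roi.reshape(g, patch_side, g, patch_side).transpose(0, 2, 1, 3)
    return tiled.reshape(g * g, patch_side, patch_side)


def assemble_patches(patches: np.ndarray) -> np.ndarray:
    """Inverse of :func:`extract_patches` for a square patch grid."""
    patches = np.asarray(patches)
    n, p, _ = patches.shape
    g = int(round(np.sqrt(n)))
    if g * g != n:
        raise ValueError("patch count is not a perfect square")
    return patches.reshape(g, g, p, p).transpose(0, 2, 1, 3).reshape(g * p, g * p)


def reduce_patch(patch: np.ndarray, mode: str = "row_mean") -> tuple[float, float]:
    """Collapse a 2x2 patch ((a, b), (c, d)) to the two encoder inputs.

    ``row_mean`` -> ((a+b)/2, (c+d)/2) uses all four pixels; ``first_two``
    -> (a, b) is the literal minimal selection.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (2, 2):
        raise ValueError(f"patch must be 2x2, got {patch.shape}")
    if mode == "row_mean":
        return (float(patch[0].mean()), float(patch[1].mean()))
    if mode == "first_two":
        return (float(patch[0, 0]), float(patch[0, 1]))
    raise ValueError(f"unknown reduction mode {mode!r}")


def reduce_patches(patches: np.ndarray, mode: str = "row_mean") -> np.ndarray:
    """Vectorized :func:`reduce_patch` over a stack of 2x2 patches."""
    patches = np.asarray(patches, dtype=float)
    if patches.shape[1:] != (2, 2):
        raise ValueError("patches must be 2x2")
    if mode == "row_mean":
        return patches.mean(axis=2)
    if mode == "first_two":
        return patches[:, 0, :]
    raise ValueError(f"unknown reduction mode {mode!r}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB -> grayscale by channel (luminance) average; grayscale passthrough."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image.mean(axis=2)
    return image


def resize_image(image: np.ndarray, target_side: int) -> np.ndarray:
    """Bilinear resize to a square canvas."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if (h, w) == (target_side, target_side):
        return image
    factors = (target_side / h, target_side / w)
    out = ndimage.zoom(image, factors, order=1, mode="nearest", grid_mode=True)
    return out[:target_side, :target_side]


def prepare_roi(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Full deterministic front end for the quantum stage.

    Grayscale conversion, bilinear resize to ``target_side``, centered crop to
    ``roi_side``, clipped to [0, 1] so the angle encoding stays in [0, pi].
    """
    gray = to_grayscale(image)
    resized = resize_image(gray, config.target_side)
    roi = center_crop(resized, config.roi_side)
    return np.clip(roi, 0.0, 1.0)


def load_image_dir(root: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a directory-per-class tree of PNG/JPEG images.

    Returns float images scaled to [0, 1], integer labels, and the sorted
    class names.  Counterpart of the synthetic generator's PNG writer.
    """
    from PIL import Image  # local import: only needed for the file interface

    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels, names = [], [], []
    for k, d in enumerate(class_dirs):
        names.append(d.name)
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            arr = np.asarray(Image.open(f), dtype=float)
            arr = to_grayscale(arr) / 255.0
            images.append(arr)
            labels.append(k)
    return np.stack(images), np.asarray(labels, dtype=int), names
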