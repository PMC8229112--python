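"""Image standardization: patch-wise gray-world color constancy, center crop,
bicubic resize, dataset-mean subtraction.

The gray-world variant estimates the scene illuminant from the average color
of rectangular patches rather than raw pixels, which smooths the influence of
a locally dominant color (the lesion itself).  The correction divides each
channel by its illuminant component; the estimate is normalized so its
largest component is 1, so correction can only darken and clipping is
minimized.  The fixed pipeline order is gray-world -> crop -> resize ->
mean-subtract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "IlluminantEstimate",
    "PipelineConfig",
    "IMAGENET_MEAN_RGB",
    "ILLUMINANT_FLOOR",
    "estimate_illuminant",
    "apply_gray_world",
    "center_crop",
    "resize_bicubic",
    "subtract_dataset_mean",
    "preprocess_image",
]

#: Published ImageNet per-channel means on the [0, 1] scale.
IMAGENET_MEAN_RGB: tuple[float, float, float] = (0.485, 0.456, 0.406)

#: Lower bound applied to illuminant components so degenerate (all-zero)
#: channels never blow up the division.
ILLUMINANT_FLOOR: float = 1e-4


@dataclass(frozen=True)
class IlluminantEstimate:
    """Per-channel illuminant (e_R, e_G, e_B), normalization scalar ``k`` such
    that ``max_c e_c = 1``, and the number of patches used."""

    e: tuple[float, float, float]
    k: float
    n_patches: int

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.e):
            raise ValueError("illuminant components must be strictly positive")


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return image


def _patch_edges(length: int, n: int) -> np.ndarray:
    # uniform cuts; remainder rows/cols are absorbed by the edge patches
    return np.linspace(0, length, n + 1).round().astype(int)


def estimate_illuminant(image: np.ndarray, grid: tuple[int, int] = (4, 4)) -> IlluminantEstimate:
    """Patch-wise gray-world illuminant estimate.

    The image is divided into a ``grid[0] x grid[1]`` array of rectangular
    patches; each patch contributes its mean color with equal weight, and the
    per-channel average over patches is rescaled so the largest component
    equals 1.
    """
    image = _validate_image(image)
    gr, gc = grid
    if gr < 1 or gc < 1:
        raise ValueError("grid must contain at least one patch")
    h, w = image.shape[:2]
    rows = _patch_edges(h, min(gr, h))
    cols = _patch_edges(w, min(gc, w))
    patch_means = []
    for r0, r1 in zip(rows[:-1], rows[1:]):
        for c0, c1 in zip(cols[:-1], cols[1:]):
            patch_means.append(image[r0:r1, c0:c1].mean(axis=(0, 1)))
    mean_of_means = np.mean(patch_means, axis=0)
    if np.any(mean_of_means < ILLUMINANT_FLOOR):
        logger.warning("near-zero channel in illuminant estimate; floor applied")
        warnings.warn("near-zero channel in illuminant estimate; floor applied", stacklevel=2)
    floored = np.maximum(mean_of_means, ILLUMINANT_FLOOR)
    k = float(floored.max())
    e = floored / k
    return IlluminantEstimate(e=tuple(float(c) for c in e), k=k, n_patches=len(patch_means))


def apply_gray_world(image: np.ndarray, est: IlluminantEstimate) -> np.ndarray:
    """Divide each channel by its illuminant component and clip to [0, 1]."""
    image = _validate_image(image)
    corrected = image / np.asarray(est.e)[None, None, :]
    return np.clip(corrected, 0.0, 1.0)


def center_crop(image: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Crop a centered ``out_size`` window; fractional offsets round toward
    the top-left (offset = floor((in - out) / 2))."""
    image = _validate_image(image)
    h, w = image.shape[:2]
    oh, ow = out_size
    if oh > h or ow > w:
        raise ValueError(f"crop size {out_size} exceeds image size {(h, w)}")
    r0 = (h - oh) // 2
    c0 = (w - ow) // 2
    return image[r0 : r0 + oh, c0 : c0 + ow].copy()


def resize_bicubic(image: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Bicubic resize to ``out_size``; output clipped to [0, 1]."""
    image = _validate_image(image)
    if out_size[0] < 1 or out_size[1] < 1:
        raise ValueError("out_size must be >= 1 in both dims")
    if tuple(image.shape[:2]) == tuple(out_size):
        return image.copy()
    out = _sk_resize(
        image, (out_size[0], out_size[1], 3), order=3, mode="reflect",
        anti_aliasing=out_size[0] < image.shape[0] or out_size[1] < image.shape[1],
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def subtract_dataset_mean(
    image: np.ndarray, mean_rgb: tuple[float, float, float] = IMAGENET_MEAN_RGB
) -> np.ndarray:
    """Subtract a per-channel dataset mean; the output is not clipped and may
    be negative."""
    image = _validate_image(image)
    mean = np.asarray(mean_rgb, dtype=float)
    if np.any(mean < 0) or np.any(mean > 1):
        raise ValueError("mean_rgb components must lie in [0, 1]")
    return image - mean[None, None, :]


@dataclass(frozen=True)
class PipelineConfig:
    """Standardization pipeline settings; ``order`` records and enforces the
    fixed stage order."""

    grid: tuple[int, int] = (4, 4)
    crop_size: tuple[int, int] | None = (450, 450)
    resize_size: tuple[int, int] | None = (224, 224)
    mean_rgb: tuple[float, float, float] | None = IMAGENET_MEAN_RGB
    color_constancy: bool = True
    order: tuple[str, ...] = ("gray_world", "crop", "resize", "mean_subtract")

    def __post_init__(self) -> None:
        if self.order != ("gray_world", "crop", "resize", "mean_subtract"):
            raise ValueError("pipeline order is fixed: gray_world, crop, resize, mean_subtract")


def preprocess_image(image: np.ndarray, config: PipelineConfig = PipelineConfig()) -> np.ndarray:
    """Run the full standardization pipeline on one image.

    Stages with a ``None`` setting (and gray-world when ``color_constancy`` is
    off) are skipped; the relative order never changes.
    """
    out = _validate_image(image)
    if config.color_constancy:
        out = apply_gray_world(out, estimate_illuminant(out, config.grid))
    if config.crop_size is not None:
        out = center_crop(out, config.crop_size)
    if config.resize_size is not None:
        out = resize_bicubic(out, config.resize_size)
    if config.mean_rgb is not None:
        out = subtract_dataset_mean(out, config.mean_rgb)
    return out
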