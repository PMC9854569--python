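"""File I/O: images as PNG/TIFF, label maps as 16-bit TIFF, target caches."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_image", "read_labels", "write_labels", "write_targets", "read_targets", "write_overlay"]


def read_image(path) -> np.ndarray:
    """Single-channel grayscale image from PNG or TIFF."""
    path = Path(path)
    arr = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1).astype(arr.dtype)
    return arr


def read_labels(path) -> np.ndarray:
    labels = tifffile.imread(path)
    if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"{path}: label maps must be 2-D integer TIFFs")
    return labels


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot be stored as uint16")
    tifffile.imwrite(path, labels.astype(np.uint16))


def write_targets(path, prob: np.ndarray, dist: np.ndarray) -> None:
    """Cache (prob, dist) targets as one multi-channel float32 TIFF."""
    stack = np.concatenate([prob[None], dist.transpose(2, 0, 1)], axis=0)
    tifffile.imwrite(path, stack.astype(np.float32))


def read_targets(path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(path)
    return stack[0], stack[1:].transpose(1, 2, 0)


def write_overlay(path, image: np.ndarray, labels: np.ndarray) -> None:
    """PNG of the grayscale image with instance boundaries tinted per id."""
    from scipy import ndimage

    img = np.asarray(image, dtype=np.float64)
    if img.max() > 0:
        img = 255.0 * img / img.max()
    rgb = np.stack([img] * 3, axis=-1)
    rng = np.random.default_rng(0)
    for k in np.unique(labels):
        if k == 0:
            continue
        mask = labels == k
        edge = mask & ~ndimage.binary_erosion(mask)
        rgb[edge] = rng.integers(64, 256, size=3)
    iio.imwrite(path, rgb.clip(0, 255).astype(np.uint8))
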