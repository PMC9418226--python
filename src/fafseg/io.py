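"""Reading and writing the package's standard file formats.

Images are 8- or 16-bit grayscale PNG/TIFF, rescaled linearly by bit
depth to [0, 1] floats on read.  Masks are single-channel PNGs with the
convention 0 = background, 255 = atrophy, mapped to {0, 1} on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_sample", "read_image", "read_mask", "write_image", "write_mask"]


def _as_gray(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0]
        if arr.shape[2] in (3, 4) and (arr[..., :3] == arr[..., :1]).all():
            return arr[:, :, 0]  # gray stored as RGB
        raise ValueError(
            f"{path}: RGB image given; convert to single-channel grayscale first"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def read_image(path) -> np.ndarray:
    """Read a grayscale image and rescale to [0, 1] floats by bit depth."""
    arr = _as_gray(iio.imread(path), path)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_mask(path) -> np.ndarray:
    """Read a {0, 255} mask PNG as a strict {0, 1} uint8 array."""
    arr = _as_gray(iio.imread(path), path)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(
            f"{path}: mask values must be in {{0, 255}}; found {vals[:8]}"
        )
    return (arr == 255).astype(np.uint8)


def read_sample(image_path, mask_path=None):
    """Read an image (and optionally its mask); see module docstring."""
    image = read_image(image_path)
    if mask_path is None:
        return image, None
    mask = read_mask(mask_path)
    if mask.shape != image.shape:
        raise ValueError(
            f"image/mask shape mismatch: {image.shape} vs {mask.shape} "
            f"({image_path} / {mask_path})"
        )
    return image, mask


def write_image(path, image: np.ndarray) -> None:
    """Quantize a [0, 1] float image to 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as a {0, 255} single-channel PNG."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("write_mask expects a binary {0,1} mask")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
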