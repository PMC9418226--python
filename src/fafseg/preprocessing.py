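"""Image standardization: black-border removal and resizing to a fixed square.

Acquisition devices pad some fundus-autofluorescence exports with a
black border at the image bottom.  The border is detected as the
maximal run of terminal rows whose mean intensity falls at or below a
dark threshold, cropped from both the image and its label, and the pair
is then resized to a constant square size (bilinear for images,
nearest-neighbour for masks so labels stay strictly binary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["BorderReport", "detect_black_border", "standardize", "rescale_intensity", "Standardizer"]


@dataclass(frozen=True)
class BorderReport:
    """Location of the terminal black border: first row index and row count."""

    first_border_row: int | None
    n_border_rows: int


def rescale_intensity(image: np.ndarray) -> np.ndarray:
    """Linear rescale to [0, 1] floats by bit depth (integer inputs) or clip."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float64) / np.iinfo(image.dtype).max
    return np.clip(image.astype(np.float64), 0.0, 1.0)


def detect_black_border(image: np.ndarray, dark_threshold: float = 0.02) -> BorderReport:
    """Find the contiguous run of dark rows at the image bottom.

    A row belongs to the border iff its mean intensity is <= the
    threshold (on the [0, 1] scale) and every row below it is border as
    well; rows that contain bright pixels raising the mean above the
    threshold terminate the run.
    """
    image = rescale_intensity(image)
    if image.size == 0:
        raise ValueError("detect_black_border: empty image")
    row_means = image.mean(axis=1)
    n = 0
    for mean in row_means[::-1]:
        if mean <= dark_threshold:
            n += 1
        else:
            break
    if n == len(row_means):
        raise ValueError("entire image is below the dark threshold; degenerate input")
    first = len(row_means) - n if n > 0 else None
    return BorderReport(first_border_row=first, n_border_rows=n)


def standardize(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    target_size: int | tuple[int, int] = 768,
    dark_threshold: float = 0.02,
    rescale: bool = True,
):
    """Crop the bottom black border, then resize to ``target_size`` square.

    The crop is applied before the resize (the order is observable on
    bordered inputs), and identically to the image and its mask.  Masks
    are resampled with nearest-neighbour interpolation and returned as
    strict {0, 1} uint8.  Returns the image alone when no mask is given.
    """
    image = np.asarray(image)
    if isinstance(target_size, int):
        target_size = (target_size, target_size)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != image.shape:
            raise ValueError(
                f"image/mask shape mismatch: {image.shape} vs {mask.shape}"
            )
        if not np.isin(np.unique(mask), (0, 1)).all():
            raise ValueError("standardize expects a binary {0,1} mask")

    image = rescale_intensity(image) if rescale else np.asarray(image, dtype=np.float64)
    report = detect_black_border(image, dark_threshold)
    if report.n_border_rows > 0:
        image = image[: report.first_border_row]
        if mask is not None:
            mask = mask[: report.first_border_row]

    if image.shape != tuple(target_size):
        image = resize(image, target_size, order=1, anti_aliasing=True, preserve_range=True)
    if mask is not None and mask.shape != tuple(target_size):
        mask = resize(
            mask.astype(np.uint8), target_size, order=0, anti_aliasing=False,
            preserve_range=True,
        )
    if mask is not None:
        mask = (np.asarray(mask) > 0.5).astype(np.uint8)
        return image, mask
    return image


class Standardizer(BaseEstimator, TransformerMixin):
    """Stateless transformer applying :func:`standardize` to image stacks.

    ``transform`` accepts an (n, H, W) stack of images; use
    :meth:`transform_pair` for an image with its label.
    """

    def __init__(self, target_size: int = 768, dark_threshold: float = 0.02,
                 rescale: bool = True):
        self.target_size = target_size
        self.dark_threshold = dark_threshold
        self.rescale = rescale

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack(
            [
                standardize(
                    img, target_size=self.target_size,
                    dark_threshold=self.dark_threshold, rescale=self.rescale,
                )
                for img in X
            ]
        )

    def transform_pair(self, image, mask):
        return standardize(
            image, mask, target_size=self.target_size,
            dark_threshold=self.dark_threshold, rescale=self.rescale,
        )
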