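"""Grayscale ROI images: container, loading, and bounding-box cropping.

The analysis unit is an 8-bit grayscale crop of a manually delineated tumor
region of interest.  An optional binary mask marks the ROI; what is
decomposed downstream is the tight rectangular bounding box of that mask
(wavelet coefficients have no one-to-one pixel mapping, so the irregular
mask itself is not applied to coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["GrayImage", "crop_to_roi", "load_gray_image", "save_gray_image", "MIN_ROI_SIDE"]

#: Minimum side length of a croppable ROI (level-3 decomposition needs room).
MIN_ROI_SIDE = 8


@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale pixel matrix with an optional binary ROI mask."""

    pixels: np.ndarray
    mask: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.mask is not None:
            m = np.asarray(self.mask).astype(bool)
            if m.shape != px.shape:
                raise ValueError("mask shape must match pixels")
            if not m.any():
                raise ValueError("mask is empty")
            object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def crop_to_roi(image: GrayImage) -> GrayImage:
    """Crop to the tight bounding box of the mask (identity if no mask).

    Raises
    ------
    ValueError
        If the bounding box is smaller than ``MIN_ROI_SIDE`` in either
        dimension.
    """
    if image.mask is None:
        box = image.pixels
    else:
        rows = np.flatnonzero(image.mask.any(axis=1))
        cols = np.flatnonzero(image.mask.any(axis=0))
        box = image.pixels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if min(box.shape) < MIN_ROI_SIDE:
        raise ValueError(
            f"ROI crop {box.shape} smaller than {MIN_ROI_SIDE}x{MIN_ROI_SIDE} "
            f"(subject {image.subject_id!r})"
        )
    return GrayImage(pixels=box, mask=None, subject_id=image.subject_id)


def load_gray_image(path: str | Path, mask_path: str | Path | None = None,
                    subject_id: str | None = None) -> GrayImage:
    """Load a BMP/PNG image as 8-bit grayscale.

    Multi-channel inputs are converted by the luminosity transform with a
    warning; a mask image (same size, nonzero = ROI) may accompany it.
    """
    path = Path(path)
    img = Image.open(path)
    if img.mode != "L":
        warnings.warn(
            f"{path.name}: mode {img.mode!r} converted to 8-bit grayscale by luminosity",
            stacklevel=2,
        )
        img = img.convert("L")
    pixels = np.asarray(img)
    mask = None
    if mask_path is not None:
        m = Image.open(mask_path)
        if m.mode != "L":
            m = m.convert("L")
        mask = np.asarray(m) > 0
    return GrayImage(pixels=pixels, mask=mask,
                     subject_id=subject_id if subject_id is not None else path.stem)


def save_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write the pixel matrix as an 8-bit BMP or PNG (by extension)."""
    Image.fromarray(image.pixels, mode="L").save(path)
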