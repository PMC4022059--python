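"""Calibrated image data model and shared imaging primitives.

Every micrograph in the pipeline is carried as a :class:`CalibratedImage`:
a 2-D grayscale pixel grid tagged with the physical edge length of one
pixel (``pixel_length``, typically µm/pixel for micrographs and mm/pixel
for flatbed scans).  Intensities are held as floats on a nominal 0–255
scale and are never re-quantized, so dynamic-range rescaling and
standard deviations are exact.

Coordinates are 0-based, half-open, row-major (row = image y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CalibratedImage",
    "ROI",
    "BinaryMask",
    "DegenerateImageError",
    "load_image",
    "extract_roi",
    "rescale_dynamic_range",
    "threshold_mask",
]


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined for the given image content
    (e.g. rescaling a constant image, Otsu on a flat field)."""


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest: 0-based, half-open pixel bounds."""

    row_start: int
    col_start: int
    row_stop: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop):
            raise ValueError(f"invalid row bounds [{self.row_start}, {self.row_stop})")
        if not (0 <= self.col_start < self.col_stop):
            raise ValueError(f"invalid col bounds [{self.col_start}, {self.col_stop})")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    @property
    def n_pixels(self) -> int:
        r, c = self.shape
        return r * c

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop))

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.row_stop <= other.row_start
            or other.row_stop <= self.row_start
            or self.col_stop <= other.col_start
            or other.col_stop <= self.col_start
        )


@dataclass
class CalibratedImage:
    """2-D grayscale image with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D float array of intensities, nominally on a 0–255 scale.
    pixel_length
        Physical length of one pixel edge, in ``units`` per pixel.
    units
        Length unit tag for ``pixel_length`` (e.g. ``"um"``, ``"mm"``).
    source_id
        Free-text provenance label.
    """

    pixels: np.ndarray
    pixel_length: float
    units: str = "um"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if not (self.pixel_length > 0):
            raise ValueError("pixel_length must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean pixel grid sharing the calibration of the image it came from."""

    pixels: np.ndarray
    pixel_length: float
    units: str = "um"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not (self.pixel_length > 0):
            raise ValueError("pixel_length must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_image(path: str | Path, pixel_length: float, units: str = "um") -> CalibratedImage:
    """Read a TIFF or PNG micrograph as a calibrated grayscale image.

    Multi-channel input is collapsed to luminance by an equal-weight
    channel mean (the micrographs this pipeline targets are effectively
    grayscale).  Intensities are preserved as stored.
    """
    path = Path(path)
    if not (pixel_length > 0):
        raise ValueError("pixel_length must be positive")
    if not path.exists():
        raise FileNotFoundError(path)
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable or unsupported format
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        # drop alpha if present, then average channels
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return CalibratedImage(arr, pixel_length, units=units, source_id=path.name)


def extract_roi(img: CalibratedImage, roi: ROI) -> CalibratedImage:
    """Crop ``img`` to ``roi``; calibration is preserved."""
    nrow, ncol = img.shape
    if roi.row_stop > nrow or roi.col_stop > ncol:
        raise IndexError(f"ROI {roi} exceeds image extent {img.shape}")
    return CalibratedImage(
        img.pixels[roi.slices()].copy(),
        img.pixel_length,
        units=img.units,
        source_id=img.source_id,
    )


def rescale_dynamic_range(img: CalibratedImage) -> CalibratedImage:
    """Linearly stretch intensities so min maps to 0 and max to 255.

    This is the normalization applied to each ROI before the roughness
    statistic is taken; it makes the statistic invariant to positive
    affine intensity changes (brightness/contrast of the micrograph).

    Raises
    ------
    DegenerateImageError
        If the image is constant (the stretch is undefined).
    """
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if hi == lo:
        raise DegenerateImageError("constant image has no dynamic range to maximize")
    out = (img.pixels - lo) * (255.0 / (hi - lo))
    return CalibratedImage(out, img.pixel_length, units=img.units, source_id=img.source_id)


def threshold_mask(img: CalibratedImage, T: float, polarity: str = "above") -> BinaryMask:
    """Binary mask of pixels strictly above (or below) an intensity threshold.

    Ties (intensity exactly equal to ``T``) are classified as background
    under either polarity — a fixed, documented rule.
    """
    if not np.isfinite(T):
        raise ValueError("threshold must be finite")
    if polarity == "above":
        m = img.pixels > T
    elif polarity == "below":
        m = img.pixels < T
    else:
        raise ValueError(f"polarity must be 'above' or 'below', got {polarity!r}")
    return BinaryMask(m, img.pixel_length, units=img.units)
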