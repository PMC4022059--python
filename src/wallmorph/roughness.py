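"""SEM surface-roughness factor from grayscale dispersion in ROIs.

In low-vacuum SEM the local contrast tracks changes in surface slope, so
the dispersion of pixel intensities within a small region of interest is
a relative proxy for exposed surface roughness (not a physical height
measurement).  Each square ROI is independently rescaled to the full
0–255 dynamic range and the population standard deviation of the
rescaled values is its roughness; a sample condition is summarized by
the mean and SD of the per-ROI roughness over all ROIs (the reference
protocol takes six 0.5 µm ROIs from each of three micrographs, 18 values
per condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ROI, CalibratedImage, extract_roi, rescale_dynamic_range

__all__ = ["RoughnessResult", "roughness_of_roi", "roughness_summary", "grid_rois"]


@dataclass
class RoughnessResult:
    per_roi_sd: list[float]
    micrograph_ids: list[str]
    rois: list[ROI] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return len(self.per_roi_sd)

    @property
    def mean_sd(self) -> float:
        return float(np.mean(self.per_roi_sd))

    @property
    def sd_of_sd(self) -> float:
        return float(np.std(self.per_roi_sd))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "micrograph": self.micrograph_ids,
                "row_start": [r.row_start for r in self.rois],
                "col_start": [r.col_start for r in self.rois],
                "row_stop": [r.row_stop for r in self.rois],
                "col_stop": [r.col_stop for r in self.rois],
                "roughness_sd": self.per_roi_sd,
            }
        )


def roughness_of_roi(img: CalibratedImage, roi: ROI) -> float:
    """Roughness of one ROI: population SD of its dynamic-range-rescaled
    intensities (0–255 scale).

    The per-ROI rescale makes the statistic invariant to positive affine
    intensity changes, so micrographs taken at different brightness or
    contrast settings remain comparable.  A constant ROI has no defined
    roughness and raises.
    """
    if roi.n_pixels < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    sub = extract_roi(img, roi)
    sub = rescale_dynamic_range(sub)  # raises DegenerateImageError if constant
    return float(sub.pixels.std())


def grid_rois(
    image_shape: tuple[int, int], n: int, side_px: int, border_px: int | None = None
) -> list[ROI]:
    """Deterministic grid of ``n`` square ROIs avoiding the image border."""
    nrow, ncol = image_shape
    if border_px is None:
        border_px = max(1, side_px // 2)
    usable_r = nrow - 2 * border_px - side_px
    usable_c = ncol - 2 * border_px - side_px
    if usable_r < 0 or usable_c < 0:
        raise IndexError(f"ROI side {side_px} px does not fit in image {image_shape}")
    # near-square grid layout: gcols x grows >= n
    gcols = int(np.ceil(np.sqrt(n)))
    grows = int(np.ceil(n / gcols))
    rois = []
    for k in range(n):
        i, j = divmod(k, gcols)
        r0 = border_px + int(round(usable_r * (i + 0.5) / grows))
        c0 = border_px + int(round(usable_c * (j + 0.5) / gcols))
        rois.append(ROI(r0, c0, r0 + side_px, c0 + side_px))
    return rois


def roughness_summary(
    images: list[CalibratedImage],
    rois_per_image: int = 6,
    roi_side: float = 0.5,
    selection: str = "grid",
    seed: int | None = None,
    roi_lists: list[list[ROI]] | None = None,
) -> RoughnessResult:
    """Roughness over many ROIs across micrographs of one sample condition.

    Parameters
    ----------
    roi_side
        ROI edge length in the images' physical units (default 0.5 µm);
        converted per image to pixels by rounding, floored at 2 px.
    selection
        ``"grid"`` — deterministic grid avoiding borders (default);
        ``"random"`` — uniform placement with ``seed``;
        ``"manual"`` — use ``roi_lists`` (one list of ROIs per image),
        matching hand-selected regions.
    """
    if not images:
        raise ValueError("at least one image required")
    sds: list[float] = []
    ids: list[str] = []
    rois_used: list[ROI] = []
    rng = np.random.default_rng(seed)
    for i, img in enumerate(images):
        side_px = max(2, int(round(roi_side / img.pixel_length)))
        nrow, ncol = img.shape
        if side_px > min(nrow, ncol):
            raise IndexError(
                f"ROI side {side_px} px exceeds image {img.shape} "
                f"(roi_side={roi_side} {img.units})"
            )
        if selection == "grid":
            rois = grid_rois(img.shape, rois_per_image, side_px)
        elif selection == "random":
            rois = []
            for _ in range(rois_per_image):
                r0 = int(rng.integers(0, nrow - side_px + 1))
                c0 = int(rng.integers(0, ncol - side_px + 1))
                rois.append(ROI(r0, c0, r0 + side_px, c0 + side_px))
        elif selection == "manual":
            if roi_lists is None or len(roi_lists) != len(images):
                raise ValueError("manual selection requires one ROI list per image")
            rois = roi_lists[i]
        else:
            raise ValueError(f"unknown selection {selection!r}")
        for roi in rois:
            sds.append(roughness_of_roi(img, roi))
            ids.append(img.source_id or f"image{i}")
            rois_used.append(roi)
    return RoughnessResult(sds, ids, rois_used)
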