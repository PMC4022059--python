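"""Ground-truthed synthetic micrographs for the four imaging modalities.

Real pretreated-biomass image sets are rarely shareable, so every
pipeline stage here is exercised on synthetic images whose ground truth
is known by construction:

* :func:`make_particle_field` — dark ellipses on a bright field, like a
  flatbed scan of dispersed particles, with controlled area and
  aspect-ratio distributions and an optional fraction of touching pairs.
* :func:`make_cell_lattice` — bright cell walls of uniform thickness on
  a dark lumen, like an acriflavine-stained confocal section; a fraction
  of shared walls can be "dislocated" (split at the middle lamella into
  two parallel half-walls separated by a gap).
* :func:`make_textured_surface` — i.i.d. Gaussian texture of known
  intensity SD, the statistical structure the SEM roughness factor
  assumes.
* :func:`make_tem_wall` — a wall-intensity field containing elongated
  void lamellae of known area fraction plus a pure-void reference region
  (the "cell lumen"), as used by the reference-void threshold rule.

Each generator is a pure function of its arguments including the seed,
and returns machine-readable truth sufficient to compute the expected
downstream measurement without re-deriving geometry.  Generated
intensities lie in [0, 255]; Gaussian noise is clipped there, which
biases the realized SD slightly, so mean intensities are kept ≥ 4σ from
the clip boundaries wherever SD recovery is asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BinaryMask, CalibratedImage, ROI

__all__ = [
    "ParticleTruth",
    "ParticleFieldTruth",
    "LatticeTruth",
    "TemWallTruth",
    "CapacityError",
    "make_particle_field",
    "make_cell_lattice",
    "make_textured_surface",
    "make_tem_wall",
]


class CapacityError(RuntimeError):
    """Requested geometry cannot be placed within the image."""


@dataclass(frozen=True)
class ParticleTruth:
    """Ground truth for one synthetic particle (an ellipse)."""

    center: tuple[float, float]  # (row, col)
    major_px: float  # full major axis length, pixels
    minor_px: float
    orientation: float  # radians, from the row axis
    area_px: int  # rasterized pixel count of the ellipse alone
    aspect_ratio: float


@dataclass
class ParticleFieldTruth:
    particles: list[ParticleTruth]
    background_intensity: float
    foreground_intensity: float
    n_touching_pairs: int

    @property
    def count(self) -> int:
        return len(self.particles)


@dataclass
class LatticeTruth:
    wall_thickness_px: int
    cell_diameter_px: int
    n_cells: int
    dislocation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.wall_thickness_px < 1:
            raise ValueError("wall_thickness_px must be >= 1")
        if not (0.0 <= self.dislocation_fraction <= 1.0):
            raise ValueError("dislocation_fraction must lie in [0, 1]")


@dataclass
class TemWallTruth:
    void_fraction: float  # percent of the intra-wall ROI area
    void_intensity_mean: float
    void_intensity_sd: float
    wall_intensity_mean: float
    wall_intensity_sd: float
    void_reference_roi: ROI
    intra_wall_roi: ROI

    def __post_init__(self) -> None:
        if not (0.0 <= self.void_fraction <= 100.0):
            raise ValueError("void_fraction must lie in [0, 100]")
        if self.void_intensity_sd < 0 or self.wall_intensity_sd < 0:
            raise ValueError("intensity SDs must be non-negative")
        if self.void_reference_roi.overlaps(self.intra_wall_roi):
            raise ValueError("reference and intra-wall ROIs must not overlap")


def _ellipse_stencil(shape, center, a, b, theta):
    """Boolean stencil of an ellipse with semi-axes a >= b, rotated by theta."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_particle_field(
    n: int,
    area_dist: tuple[float, float] = (math.log(300.0), 0.5),
    aspect_dist: tuple[float, float] = (1.8, 0.4),
    touching_fraction: float = 0.0,
    image_size: tuple[int, int] = (512, 512),
    seed: int = 0,
    pixel_length: float = 0.010583,
    units: str = "mm",
    background_intensity: float = 220.0,
    foreground_intensity: float = 60.0,
    noise_sd: float = 3.0,
) -> tuple[CalibratedImage, ParticleFieldTruth]:
    """Simulate a flatbed scan: dark elliptical particles on a bright field.

    Areas are log-normal (``area_dist`` = (log-mean, log-sd) of pixel
    area); aspect ratios are normal (truncated at 1).  A fraction
    ``touching_fraction`` of the particles are deliberately placed
    overlapping a neighbor so watershed splitting can be exercised; the
    rest are placed with a clearance margin.  The default calibration is
    a 2,400 dpi scan (10.583 µm/pixel, expressed in mm).

    Returns the image and a truth table listing every particle; the
    truth ``area_px`` is the rasterized pixel count of that ellipse
    drawn alone.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= touching_fraction <= 1.0):
        raise ValueError("touching_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = tuple(image_size)

    areas = np.exp(rng.normal(area_dist[0], area_dist[1], size=n))
    aspects = np.maximum(rng.normal(aspect_dist[0], aspect_dist[1], size=n), 1.0)
    thetas = rng.uniform(0.0, math.pi, size=n)
    # area = pi * a * b with aspect = a/b  =>  b = sqrt(area/(pi*aspect))
    bs = np.sqrt(areas / (np.pi * aspects))
    as_ = bs * aspects

    n_pairs = int(round(touching_fraction * n / 2.0))
    occupied = np.zeros(shape, dtype=bool)
    particles: list[ParticleTruth] = []
    stencils: list[np.ndarray] = []

    def try_place(a, b, theta, anchor=None, want_touch=False):
        max_tries = 400
        margin = 3
        for _ in range(max_tries):
            if anchor is None:
                cr = rng.uniform(a + 1, shape[0] - a - 1)
                cc = rng.uniform(a + 1, shape[1] - a - 1)
            else:
                # place near the anchor so the two ellipses overlap
                ang = rng.uniform(0, 2 * math.pi)
                dist = rng.uniform(0.4, 0.8) * (anchor[1] + b)
                cr = anchor[0][0] + dist * math.cos(ang)
                cc = anchor[0][1] + dist * math.sin(ang)
                if not (a < cr < shape[0] - a and a < cc < shape[1] - a):
                    continue
            st = _ellipse_stencil(shape, (cr, cc), a, b, theta)
            if want_touch:
                anchor_st = anchor[2]
                if not (st & anchor_st).any():
                    continue
                # must not hit anything other than its designated partner
                if (st & occupied & ~anchor_st).any():
                    continue
            else:
                from scipy.ndimage import binary_dilation

                grown = binary_dilation(st, iterations=margin)
                if (grown & occupied).any():
                    continue
            return (cr, cc), st
        raise CapacityError(
            f"could not place particle of semi-axes ({a:.1f}, {b:.1f}) "
            f"in a {shape} image"
        )

    idx = 0
    for _ in range(n_pairs):
        placed_pair = []
        for j in range(2):
            a, b, th = as_[idx], bs[idx], thetas[idx]
            anchor = None
            if j == 1:
                prev = particles[-1]
                anchor = (prev.center, max(as_[idx - 1], bs[idx - 1]), stencils[-1])
            center, st = try_place(a, b, th, anchor=anchor, want_touch=(j == 1))
            particles.append(
                ParticleTruth(center, 2 * a, 2 * b, th, int(st.sum()), a / b)
            )
            stencils.append(st)
            occupied |= st
            idx += 1
    while idx < n:
        a, b, th = as_[idx], bs[idx], thetas[idx]
        center, st = try_place(a, b, th)
        particles.append(ParticleTruth(center, 2 * a, 2 * b, th, int(st.sum()), a / b))
        stencils.append(st)
        occupied |= st
        idx += 1

    img = np.full(shape, background_intensity, dtype=float)
    img[occupied] = foreground_intensity
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 255.0)

    truth = ParticleFieldTruth(
        particles=particles,
        background_intensity=background_intensity,
        foreground_intensity=foreground_intensity,
        n_touching_pairs=n_pairs,
    )
    cimg = CalibratedImage(img, pixel_length, units=units, source_id=f"synthetic-scan-seed{seed}")
    return cimg, truth


def make_cell_lattice(
    truth: LatticeTruth,
    image_size: tuple[int, int] | None = None,
    seed: int = 0,
    pixel_length: float = 0.2,
    units: str = "um",
    wall_intensity: float = 210.0,
    background_intensity: float = 30.0,
    noise_sd: float = 4.0,
    gap_px: int | None = None,
) -> tuple[CalibratedImage, BinaryMask]:
    """Simulate a confocal cross-section: a grid of cells with bright walls.

    Cells are laid out on a near-square grid with pitch
    ``cell_diameter_px``.  Adjoined walls are single strips of full width
    ``wall_thickness_px`` centered on the cell boundary, so the
    boundary-distance value on their centerline is half the wall width —
    the thickness of each individual cell's wall.  A randomly chosen
    ``dislocation_fraction`` of interior (shared) wall segments are
    split at the middle lamella into two parallel strips of half width
    separated by a background gap, emulating cell–cell dislocation.

    Returns the image and the exact wall mask (the ground truth the
    thickness pipeline should recover after binarization).
    """
    w = truth.wall_thickness_px
    d = truth.cell_diameter_px
    if w >= d:
        raise ValueError("wall thickness must be smaller than the cell diameter")
    rng = np.random.default_rng(seed)

    ncell = truth.n_cells
    nrows = max(1, int(math.floor(math.sqrt(ncell))))
    ncols = int(math.ceil(ncell / nrows))
    lattice_h = nrows * d + w
    lattice_w = ncols * d + w
    if image_size is None:
        pad = 4
        image_size = (lattice_h + 2 * pad, lattice_w + 2 * pad)
    shape = tuple(image_size)
    if lattice_h > shape[0] or lattice_w > shape[1]:
        raise ValueError(f"lattice {lattice_h}x{lattice_w} does not fit in image {shape}")
    r0 = (shape[0] - lattice_h) // 2
    c0 = (shape[1] - lattice_w) // 2

    if gap_px is None:
        gap_px = max(2, w // 2)
    half = w // 2
    half_hi = w - half  # handles odd widths

    mask = np.zeros(shape, dtype=bool)

    # interior horizontal gridlines i=1..nrows-1 and vertical j=1..ncols-1
    # are shared walls; boundary lines (i=0, nrows / j=0, ncols) are outer.
    h_lines = [(i, r0 + i * d) for i in range(nrows + 1)]
    v_lines = [(j, c0 + j * d) for j in range(ncols + 1)]

    interior_segments = []  # (axis, index) for dislocation draw
    for i, _ in h_lines[1:-1]:
        interior_segments.append(("h", i))
    for j, _ in v_lines[1:-1]:
        interior_segments.append(("v", j))
    n_split = int(round(truth.dislocation_fraction * len(interior_segments)))
    split = set()
    if interior_segments and n_split:
        order = rng.permutation(len(interior_segments))
        split = {interior_segments[k] for k in order[:n_split]}

    def paint_h(center_row, split_it):
        lo, hi = c0, c0 + lattice_w
        if not split_it:
            mask[center_row - half : center_row + half_hi, lo:hi] = True
        else:
            # two half-width walls separated by a centered background gap
            hw = max(1, w // 2)
            g2 = gap_px - gap_px // 2
            mask[center_row - gap_px // 2 - hw : center_row - gap_px // 2, lo:hi] = True
            mask[center_row + g2 : center_row + g2 + hw, lo:hi] = True

    def paint_v(center_col, split_it):
        lo, hi = r0, r0 + lattice_h
        if not split_it:
            mask[lo:hi, center_col - half : center_col + half_hi] = True
        else:
            hw = max(1, w // 2)
            g2 = gap_px - gap_px // 2
            mask[lo:hi, center_col - gap_px // 2 - hw : center_col - gap_px // 2] = True
            mask[lo:hi, center_col + g2 : center_col + g2 + hw] = True

    for i, row in h_lines:
        interior = 0 < i < nrows
        paint_h(row + half, interior and ("h", i) in split)
    for j, col in v_lines:
        interior = 0 < j < ncols
        paint_v(col + half, interior and ("v", j) in split)

    img = np.full(shape, background_intensity, dtype=float)
    img[mask] = wall_intensity
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 255.0)

    cimg = CalibratedImage(img, pixel_length, units=units, source_id=f"synthetic-cslm-seed{seed}")
    return cimg, BinaryMask(mask, pixel_length, units=units)


def make_textured_surface(
    base: float = 128.0,
    sigma: float = 10.0,
    image_size: tuple[int, int] = (512, 512),
    seed: int = 0,
    pixel_length: float = 0.01,
    units: str = "um",
) -> tuple[CalibratedImage, float]:
    """Simulate an SEM surface patch: i.i.d. N(base, sigma²) intensities
    clipped to [0, 255].  Returns the image and the truth SD."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    img = np.full(tuple(image_size), base, dtype=float)
    if sigma > 0:
        img += rng.normal(0.0, sigma, size=tuple(image_size))
    img = np.clip(img, 0.0, 255.0)
    cimg = CalibratedImage(img, pixel_length, units=units, source_id=f"synthetic-sem-seed{seed}")
    return cimg, sigma


def _stripe_stencil(rng, roi_shape, target_px, stripe_height=3):
    """Elongated horizontal stripes filling exactly target_px pixels."""
    h, wdt = roi_shape
    stencil = np.zeros(roi_shape, dtype=bool)
    if target_px <= 0:
        return stencil
    if target_px >= h * wdt:
        stencil[:] = True
        return stencil
    guard = 0
    while stencil.sum() < target_px:
        guard += 1
        if guard > 10_000:
            raise CapacityError("void stencil construction did not converge")
        sh = min(stripe_height, h)
        r = int(rng.integers(0, max(1, h - sh + 1)))
        length = int(rng.integers(max(4, wdt // 4), wdt + 1))
        c = int(rng.integers(0, max(1, wdt - length + 1)))
        stencil[r : r + sh, c : c + length] = True
    # trim overshoot pixel-by-pixel from the last-filled rows (row-major order
    # from the bottom) to hit the target count exactly
    excess = int(stencil.sum()) - target_px
    if excess > 0:
        idx = np.flatnonzero(stencil.ravel())
        stencil.ravel()[idx[-excess:]] = False
    return stencil


def make_tem_wall(
    truth: TemWallTruth,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    pixel_length: float = 0.002,
    units: str = "um",
) -> tuple[CalibratedImage, TemWallTruth]:
    """Simulate a TEM section of a cell wall with intra-wall voids.

    The intra-wall ROI receives elongated void lamellae (stripes parallel
    to the wall axis) occupying exactly ``truth.void_fraction`` percent
    of its area (up to one-pixel rounding); void pixels draw from the
    void intensity law and the rest from the wall law.  The reference ROI
    (the lumen) is pure void law.  The two laws must be separated by at
    least four combined SDs so recovery by the threshold rule is
    well-posed.

    Law shapes reflect the imaging physics: void space is open resin or
    vacuum — electron-lucent, flat intensity with bounded noise — so the
    void law is uniform with the given mean and SD (support mean ±
    √3·SD); the stained wall shows granular texture and draws from a
    normal law.  The bounded void support is what makes the
    reference-anchored threshold at two reference SDs a clean separator:
    it lies strictly below every void intensity.

    Returns the image and a truth record whose ``void_fraction`` is the
    realized (rasterized) percentage.
    """
    sep = abs(truth.void_intensity_mean - truth.wall_intensity_mean)
    if sep < 4.0 * (truth.void_intensity_sd + truth.wall_intensity_sd):
        raise ValueError("void and wall intensity laws must be separated by >= 4 combined SDs")
    shape = tuple(image_size)
    for roi in (truth.void_reference_roi, truth.intra_wall_roi):
        if roi.row_stop > shape[0] or roi.col_stop > shape[1]:
            raise ValueError(f"ROI {roi} exceeds image size {shape}")
    rng = np.random.default_rng(seed)

    img = rng.normal(truth.wall_intensity_mean, truth.wall_intensity_sd, size=shape)

    # uniform void law with the requested mean and SD (bounded support)
    half_range = math.sqrt(3.0) * truth.void_intensity_sd
    vlo = truth.void_intensity_mean - half_range
    vhi = truth.void_intensity_mean + half_range

    wall_roi = truth.intra_wall_roi
    target = int(round(truth.void_fraction / 100.0 * wall_roi.n_pixels))
    stencil = _stripe_stencil(rng, wall_roi.shape, target)
    realized = 100.0 * stencil.sum() / wall_roi.n_pixels

    void_vals = rng.uniform(vlo, vhi, size=int(stencil.sum()))
    sub = img[wall_roi.slices()]
    sub[stencil] = void_vals
    img[wall_roi.slices()] = sub

    ref = truth.void_reference_roi
    img[ref.slices()] = rng.uniform(vlo, vhi, size=ref.shape)

    img = np.clip(img, 0.0, 255.0)
    cimg = CalibratedImage(img, pixel_length, units=units, source_id=f"synthetic-tem-seed{seed}")
    return cimg, replace(truth, void_fraction=realized)
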