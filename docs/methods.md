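# Methods

## Scope and data model

`wallmorph` quantifies the morphology of pretreated lignocellulosic
biomass from grayscale micrographs at four scales and correlates the
resulting structural parameters with enzymatic digestibility. All
stages operate on a `CalibratedImage`: a 2-D float intensity grid
(nominal 0–255) tagged with the physical pixel edge length *l* and its
unit. Intensities are kept as reals and never re-quantized to 8 bits,
so normalization and dispersion statistics are exact; coordinates are
0-based, half-open, row-major. Multi-channel files collapse to
luminance by an equal-weight channel mean, adequate because the target
micrographs are effectively grayscale. Pixel length is always
user-supplied — no instrument metadata is parsed — and 8-bit capture is
assumed where bit depth matters.

Wet-lab protocols (pretreatment, fixation, microscopy) and the
composition/digestibility assays are out of scope; their outputs enter
only as numeric per-sample table rows.

## Particle geometry

Scans of dispersed particles (dark on a bright field) are thresholded —
Otsu by default, justified by the strong bimodal contrast of flatbed
scans, with a fixed-threshold override — and labeled with
8-connectivity. Optionally a watershed seeded at local maxima of the
foreground Euclidean distance transform (minimum seed separation 5 px)
splits touching particles along their necks; the split reassigns
foreground pixels and erases only the 1-px watershed lines. Components
under 4 px are dropped as scanner dust. Descriptors follow the
moment-ellipse conventions of the standard particle-analysis tools:
aspect ratio = major/minor axis of the second-moment ellipse, roundness
= 4·area/(π·major²); area and perimeter are scaled by *l*² and *l*.
Deeply overlapping particles whose fused blob has a single distance peak
can remain merged — a known limit of distance-seeded watershed.

Histogram bins are left-closed/right-open; defaults are powers-of-two
area bins up to 4 mm² and unit-width aspect-ratio bins 1–20, both
user-overridable. Out-of-range values are counted separately, never
silently dropped.

## Cell wall thickness

From a binary wall mask, `distance_map` computes the exact Euclidean
distance of every wall pixel to the nearest background pixel
(scipy's exact EDT) times *l*. "Nearest boundary" is implemented as
nearest background pixel — standard distance-transform semantics; the
alternative reading (nearest wall pixel adjacent to background) differs
by at most one pixel and is not implemented. `medial_axis` uses the
distance-ridge, topology-preserving skeleton; terminal spurs shorter
than 3 px (rasterization artifacts at corners and wall ends) are pruned
by default, with the safeguard that pruning never erases a connected
component entirely. Sampling the distance map at skeleton pixels gives
the thickness samples; `raw` reports D_B directly (correct for adjoined
cells sharing a wall), `disjoined-doubled` doubles it (for cells
separated at the middle lamella, where the free wall belongs to one
cell). Raw is the default; the choice is the caller's because which
regime an image is in is a biological judgement. Summaries report
mean/SD/count, optionally pooled per cell through a label image.

Rasterization bounds: for a strip of width w px the centerline value is
ceil(w/2), so the mean raw CWT sits within half a pixel of w/2; all
thickness assertions in the tests use that half-pixel band.

## Surface roughness

Each square ROI is independently rescaled so its own min→0 and max→255
(per-ROI, not per-micrograph — the normalization is applied to "pixel
values within selected ROIs"), and its roughness is the population SD
of the rescaled values. Population rather than sample SD: at the ROI
sizes used the difference is negligible and the convention is recorded
in the output metadata. A constant ROI is an error, not 0 — the
normalization is undefined without dynamic range. The protocol default
is six 0.5 µm ROIs from each of three micrographs (18 values per
condition), summarized by their mean and SD. ROI side is given in
physical units and converted by rounding, floored at 2 px; default
placement is a deterministic border-avoiding grid, with seeded-random
and manual-list alternatives (the reference protocol picked ROIs by
hand).

A consequence of per-ROI full-range normalization worth knowing: on
*pure* stationary noise the statistic is nearly amplitude-invariant
(the stretch cancels the scale), so synthetic ranking tests plant
full-range anchor detail inside each ROI — standing in for the true
black/white detail real micrographs contain. The statistic is a
relative exposed-surface proxy, bounded by (0, 127.5], not a physical
height roughness.

## Void / delamination fraction

The threshold is anchored to a designated pure-void reference region
(the cell lumen): T = x̄_v + k·σ_v from the reference mean and
population SD. The sign of k and the classification polarity are both
exposed because the two natural readings of the rule conflict for
electron-lucent (bright) voids: defaults k = −2, polarity = above
classify as void everything brighter than two reference SDs below the
void mean, which realizes the intent of counting pixels consistent with
void space; the literal k = +2 is available. Ties are non-void. Void
percent is void pixels over ROI pixels; no morphological cleanup is
applied — the method is pure thresholding. Connected void regions are
described with the particle descriptor set; regions clipped by the ROI
border are included in the area fraction and flagged in the shape table.

## Correlation report

Each sample contributes one summary row (composition, digestibility,
structural parameters; percentages 0–100, particle size as mean
projected area in mm², thickness in µm). Every parameter is correlated
with glucan release by Pearson R, with R² stored as the exact square of
the unrounded R; display rounding is 2 dp, half-away-from-zero. The
default sample set excludes the untreated control: recomputation of the
bundled published table shows six of its eight printed R values match
the pretreated-only rows, while particle size matches the all-samples
set (−0.96 unrounded vs −0.97 printed) and degree of polymerization
(printed −0.28) matches neither subset (+0.26 pretreated-only, −0.73
all) — both modes are exposed and the discrepant columns are reported
as computed, not forced to the printed values. With n ≤ 4 no p-values
or multiple-testing machinery are provided; the correlations are
descriptive.

## Synthetic generators

All generators are pure functions of their arguments including the
seed, return machine-readable truth, and emit intensities in [0, 255].

* **Particle fields** — dark ellipses (foreground 60, background 220,
  Gaussian noise SD 3) with log-normal areas (default log-mean
  log(300 px²), log-SD 0.5) and normal aspect ratios truncated at 1
  (default 1.8 ± 0.4); a requested fraction of particles is placed
  overlapping a designated partner, the rest with a 3-px clearance.
  Bimodal (control-like) size distributions are emulated by combining
  two fields with different log-means. Truth area is the rasterized
  stencil count of each ellipse alone. Default calibration 10.583
  µm/px (2,400 dpi flatbed).
* **Cell lattices** — near-square grids of cells with bright walls
  (210 on 30, noise SD 4) of uniform width centered on the cell
  boundaries; a chosen fraction of interior (shared) wall segments is
  split into two half-width strips separated by a background gap,
  emulating middle-lamella dislocation. The returned mask is the exact
  wall truth.
* **Textured surfaces** — i.i.d. N(base, σ²) pixels clipped to
  [0, 255]. Clipping biases the realized SD, so recovery assertions
  keep the base ≥ 4σ from the clip boundaries.
* **TEM walls** — the wall draws from a normal law (granular stain
  texture); void space draws from a *uniform* law with the requested
  mean and SD (support mean ± √3·SD), reflecting electron-lucent open
  resin: flat intensity with bounded noise. The bounded support is what
  makes the reference-anchored threshold at two reference SDs a clean
  separator — it lies strictly below every void intensity, so fraction
  recovery is limited only by estimation error in x̄_v, σ_v. Void
  lamellae are elongated stripes (emulating intramural banding) filled
  to the requested area fraction exactly, up to one pixel; the returned
  truth carries the realized rasterized fraction. Generation requires
  the two laws separated by ≥ 4 combined SDs so recovery is well-posed.

What the generators do *not* emulate: real biological texture within
walls, uneven illumination, focus gradients, charging artifacts, or
particle shapes beyond ellipses. Passing recovery tests therefore
demonstrates estimator correctness on the statistical structure each
estimator assumes, not robustness to real-world imaging artifacts.

## Problem sizes and verification

The test and acceptance runs use desk-scale problems chosen to keep the
statistics meaningful: 200 random masks up to 32×32 for exact agreement
of the distance map with a brute-force all-pairs oracle; strip widths
3–15 px for the half-width identity; a 3×3 lattice with 6-px walls at
0.5 µm/px (≈ 930 centerline samples) for thickness recovery within half
a pixel; 18 ROIs per condition for roughness ranking across three noise
levels; 6 ROIs × 6 images per condition over true void fractions of 5,
25, 50 and 75 % for void recovery within 1 % absolute; 25–30-particle
fields for count and 2 %-area recovery. The published image-derived
absolute values (per-sample thickness, roughness, porosity means and
particle counts) require the original micrographs, which are not
deposited; the bundled published summary table is the input to the
correlation stage instead.

## Known limitations

* Watershed under-segments deeply fused particles (single distance
  peak); counts are a lower bound at high touching fractions.
* Medial-axis spur pruning slightly under-samples wall ends; disable it
  (`prune_spurs_px=None`) to keep every skeleton pixel.
* The roughness factor depends on the normalization convention; values
  are comparable only within a consistent ROI protocol.
* The void threshold rule assumes the reference region is genuinely
  pure void; contamination inflates σ_v and shifts T.
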