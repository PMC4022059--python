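# wallmorph

Quantitative morphometrics of pretreated lignocellulosic biomass
micrographs.

Dilute acid pretreatment opens plant cell walls for enzymatic
saccharification, and *how* it opens them depends on the reactor:
gradual depressurization, explosive steam discharge and mechanical shear
leave different fingerprints at every length scale, from millimetre
particle geometry down to nanometre delamination of wall lamellae.
`wallmorph` implements the image-analysis pipeline that turns
micrographs at four scales into comparable structural numbers, and
correlates those numbers with digestibility:

| stage | input | statistic |
|---|---|---|
| particle geometry | flatbed scans (mm scale) | area, perimeter, aspect ratio, roundness per watershed-segmented particle |
| cell wall thickness | confocal sections of stained walls (µm) | boundary-distance map sampled at the medial axis (CWT) |
| surface roughness | SEM surfaces (sub-µm) | SD of dynamic-range-normalized grayscale in square ROIs |
| void / delamination | TEM sections (nm) | % of intra-wall ROI above a reference-void threshold T = x̄_v + k·σ_v |
| correlation | per-sample summary table | Pearson R and R² of each parameter vs glucan release |

The core model for wall thickness: for a binary wall mask, the
boundary-distance function

&nbsp;&nbsp;&nbsp;&nbsp;D_B(x, y) = l · √((x − x_B)² + (y − y_B)²)

gives each wall pixel its distance to the nearest background pixel
(pixel length *l*), and evaluating D_B on the medial axis transform
MAT(x, y) yields one cell-wall thickness sample per centerline pixel:
CWT = D_B(MAT(x, y)). For adjoined cells sharing a wall the centerline
value is each cell's own wall thickness; for cells separated at the
middle lamella it is half the free wall's thickness (the
`disjoined-doubled` convention compensates).

Because micrograph sets of this kind are rarely shareable, the package
ships ground-truthed synthetic generators for all four modalities
(`wallmorph.synthetic`), so every estimator is testable against known
truth.

## Worked example

```
$ python examples/wall_thickness.py
wall width          : 6 px at 0.5 um/px
expected CWT        : 1.50 um (half the shared wall)
measured CWT        : 1.53 um  (sd 0.10, n 932 centerline samples)
disjoined-doubled   : 3.06 um (use when cells have separated and each wall belongs to one cell)
```

A 3×3 lattice of cells sharing 6-px walls at 0.5 µm/pixel is generated,
binarized, distance-transformed and skeletonized; the 932 centerline
samples average 1.53 µm against the constructed 1.50 µm (the 0.03 µm
excess is half-pixel rasterization bias). The other examples cover
particle segmentation (`particle_geometry.py`), the roughness factor
(`surface_roughness.py`), void quantification (`void_fraction.py`) and
the correlation table (`correlation_table.py`):

```
$ python examples/correlation_table.py
parameter                          R      R2    n
xylan                          -1.00    1.00    3
lignin                          0.87    0.76    3
...
delamination_porosity           1.00    1.00    3
```

Over the three pretreated reactor conditions, delamination/porosity and
surface roughness track glucan release almost perfectly, while residual
xylan and wall thickness anti-correlate — the morphological signature of
effective pretreatment.

There is also a thin CLI (`wallmorph particles | wallthickness |
roughness | voids | correlate | simulate`) for running the same stages
on image files from a shell.

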