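# Methods

## Scope and assumptions

The package quantifies structures that have already been segmented:
nuclei (e.g. StarDist), cells (e.g. a Multicut membrane segmentation),
whole-structure and lumen masks (e.g. ilastik object classification) are
inputs on the same voxel grid as the image. No segmentation is learned or
performed here; the naive geometric segmentations inside the phantom
generator exist only to make planted truth self-consistent. Structures
without a lumen are excluded from delamination and lumen-distance
analyses, which mirrors how such structures are treated in practice.

Coordinates are 0-based `(z, y, x)`; all exported lengths/areas/volumes
are physical (μm) using per-axis voxel sizes, so anisotropic confocal
stacks are handled throughout. 2D inputs are promoted to single-plane 3D
so every operation has one code path.

## Intensity normalization chain

1. **Per-plane background.** For each z-plane the background is the
   0.75 quantile of intensities inside the structure mask but outside the
   nuclear mask, and is subtracted from every pixel of the plane.
   Quantiles use sorted linear interpolation at rank `q(n−1)`. Two
   consequences are worth stating explicitly:
   - re-estimating the background of a corrected plane gives exactly 0
     (shift equivariance);
   - on a signal-free background region with Gaussian noise of SD σ the
     estimator sits `z_0.75 σ ≈ 0.674 σ` above the mean background by
     construction — the 75th percentile is chosen to be robust against
     dim signal contamination, not to be unbiased. Recovery on phantoms
     is therefore assessed as the mean absolute deviation per structure,
     which stays below one noise SD; individual planes that intersect
     only a few structure voxels (pole caps) carry quantile estimates
     from a handful of pixels and are not individually meaningful.
   - Planes with no non-nuclear structure pixels are flagged and skipped.
   Negative pixels after subtraction are kept by default to preserve
   linearity; a `clip_negative` flag exists because whether the original
   analysis clipped is not documented.
2. **DAPI normalization.** Every corrected pixel is divided by the mean
   background-corrected DAPI intensity over nuclear pixels of its plane.
   Because depth attenuation is multiplicative and common to all
   channels, the planar DAPI mean is a per-plane gauge and the ratio is
   depth-independent; this is verified on phantoms with planted
   attenuation (no significant slope of per-cell means vs depth at
   n = 200 cells, and a significant slope before normalization as the
   positive control). Joint rescaling of marker and DAPI channels leaves
   every output unchanged.
3. **Batch normalization.** Per-cell nuclear means are approximately
   log-normal, so each experiment is normalized by its geometric mean;
   the output has per-batch geometric mean exactly 1. Non-positive
   values are excluded and counted.

**Marker classification.** The original positive/negative call used a
manually trained object classifier and is not reproducible from a written
description, so explicit classifiers on the normalized nuclear mean are
provided instead: `fixed_threshold`, `otsu`, and the default `gmm2`
(two-component Gaussian mixture in log space, decision boundary at
posterior 0.5). Otsu also operates in log space when all values are
positive: the clusters of log-normal intensity data are symmetric on the
log scale, and linear-scale Otsu systematically cuts inside the skewed
tail of the negative population. Degenerate all-equal inputs raise with
advice to use a fixed threshold.

**Monolayer (2D) variant.** After the percentile subtraction, the nuclear
background level is removed as the *median* of nuclear pixels — the
stated assumption is that most nuclear pixels sit at background-level
expression, and the median is the statistic that realises that assumption
robustly (the alternative, a mean, is pulled by the bright minority).
Then pixels are divided by the mean nuclear DAPI intensity.

## Geometry

- **Surface area** comes from a marching-cubes isosurface of the binary
  mask after light Gaussian smoothing (σ = 1 voxel). Isosurfacing the raw
  binary mask inflates the area of smooth surfaces by ~8% (voxel
  staircase), which would push the sphericity of a perfect digitized ball
  to ~0.92; with smoothing a radius-20 ball reads within 0.5% of `4πr²`.
- **Ellipticity** is the longest/shortest principal *axis* ratio,
  i.e. the square root of the covariance eigenvalue ratio (for a solid
  ellipsoid the eigenvalues are `a²/5`, so the root recovers the axis
  ratio exactly).
- **"Radius of the spheroid"** for the normalized lumen distance is the
  volume-equivalent sphere radius — the only definition that is
  well-behaved for non-spherical structures.
- **Lumen counting** uses 6-connected components with a minimum volume of
  30 μm³ (≈ a 2 μm-radius sphere) to suppress segmentation specks; no
  filter was documented originally, and the default is configurable.
- **Lumen contact / delamination** replaces a manual visual call with
  mask adjacency: a cell is in contact iff any voxel lies within a
  1-voxel Chebyshev tolerance of a lumen voxel. The phantom plants
  delaminated cells ≥ 2 voxels from every lumen, so any tolerance ≤ 1
  classifies them correctly. The "cells underneath mitotic cells are not
  counted" rule is operationalized as: a non-contacting cell is excluded
  iff it touches (within 1 voxel) a mitotic cell whose centroid is closer
  to the lumen than its own. Mitotic flags are inputs (a pHH3
  classification or ground truth); no morphology-based mitosis detection.
- **Golgi angle** folds the angle between the lumen→nucleus and
  nucleus→Golgi *lines* to [0°, 90°]. With directed vectors a perfectly
  apical Golgi would score ≈ 180° and be called unpolarized by the
  documented "> 60° = unpolarized" rule, so the undirected (folded)
  convention is the only self-consistent reading; the boundary itself is
  polarized (strict inequality).
- **Circularity** `4πA/P²` uses the 4-direction Crofton perimeter, which
  is essentially unbiased for smooth outlines (digitized disk of radius
  50 px scores ≈ 0.99). For 1-pixel-thin or sharply angular objects the
  Crofton estimate under-reads the perimeter and circularity reads high
  by up to ~20%; spheroid mid-plane cross-sections, the intended input,
  are smooth blobs.

## Tip/side partition and densities

The long axis is the leading principal axis of the structure mask's
coordinate covariance, with the sign fixed deterministically; an explicit
axis override exists both for near-isotropic structures (degenerate
covariance raises) and for chambers of known orientation. Lumen voxels
are projected onto the axis; with several lumens the extrema are taken
over their union. Structure voxels beyond the extrema are `tip`, the rest
`side`; the partition is exhaustive and exclusive by construction and
tested voxel-wise. Cells are assigned by nucleus-centroid projection
(simplest rule consistent with per-cell tables). Densities are
cells · μm⁻³, or cells · μm⁻² in the documented single-plane variant.

## Profiles and bands

Junction profiles are bilinear samples at uniform sub-pixel spacing along
a segment perpendicular to the junction. The hand-drawn "horizontal
background line" of the original procedure is replaced by the mean of the
outer 25% of samples on each side, and the integrated intensity is the
trapezoidal area of the excess above that baseline, clipped at zero
(only area above the line counts). Two replicate points per junction are
placed by seeded uniform arclength sampling, standing in for "two random
points", and averaged. The aPKC band is the ZO-1 outline dilated by a
5-pixel disk (11 px across a straight segment); its mean equals the
brute-force mean over the dilated set exactly.

## Embryo-plane metrics

ROIs are input polygon annotations. Counting metrics (cell density) use
nucleus-centroid membership; area metrics (GFP contribution, chimerism)
use pixel intersection of the rasterised polygon with the masks — two
deliberately different rules matching the two documented procedures. The
GFP mask is intersected with the nuclear mask before area ratios.
Positive-cell counting in 2D fields uses 8-connected components with a
minimum object size and a 50% overlap rule for the positive call (the
original mask-intersection rule is not stated quantitatively). A global
(not per-plane) GFP threshold is assumed where thresholding is needed.

## Phantom generator

The spheroid phantom emulates the study conditions the pipeline assumes:
a monolayer of wedge-shaped cells (spherical Voronoi of quasi-uniform
shell directions) around a central lumen of radius 10 μm inside a
25 μm structure, 40 cells of which 3 are planted delaminated (attached
basally, ≥ 2 voxels from any lumen), 15% marker-positive at ×4 intensity,
ellipsoidal nuclei at 60% radial depth, per-cell log-normal expression
with ln-SD 0.15, additive per-plane background (mean 20, ±30% across
planes), multiplicative depth attenuation `a_z = exp(−0.01 z[μm])`
applied to **all** fluorescence channels (attenuation is a property of
the optical path, and applying it to the marker but reading depth
correction off DAPI is precisely what the normalization chain assumes),
and Gaussian noise of SD 2 added last with sub-zero values clipped and
counted. The ×4 positive separation with ln-SD 0.15 leaves ≈ 4.6 σ
between populations, so exact classification is expected, not lucky.

The microcavity phantom fills a 200 × 50 × 50 μm box (long axis
configurable) with an elongated lumen spanning the middle 60% of the long
axis and plants a 2:1 tip:side density ratio by sampling seeded
minimum-separation nucleus positions per region. The embryo-plane
phantom scatters identical integer-centred nuclear disks inside
non-overlapping anterior/posterior rectangles at planted densities
(1.0 and 1.5 × 10⁻³ cells μm⁻²), marks planted GFP subsets (10% / 40%),
and draws a contiguous 900 μm² marker region.

What the phantoms do *not* emulate: optical PSF blur, shot noise,
segmentation errors (masks are exact by construction), touching or
overlapping nuclei, irregular cell shapes, and mitotic figures. Passing
tests therefore demonstrate that the measurement code is correct given
correct masks; they do not bound errors introduced by real segmentation.

## Determinism, sizes, and reports

Every stochastic step (phantom generation, replicate placement, the
mixture fit) is seeded; two runs of `spq simulate` + `spq quantify3d`
with the same seed produce byte-identical CSVs, and every output records
a configuration hash. Validation uses ten 40-cell spheroid phantoms, one
200-cell phantom for the depth-trend test, five microcavity phantoms,
and analytic solids at radius 20–44 voxels — sizes chosen so the full
suite exercises every property at comfortably converged resolution.
Reports are descriptive only (mean ± SEM, contingency counts); the
original studies' inferential tests are deliberately not reproduced so
the pipeline never claims their p-values.
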