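# Methods

This note documents the models and conventions behind `loricavol`, the
calibrations that are the package's own choices, and what the synthetic
generators do and do not emulate.

## Solid-of-revolution volumes

A body with rotational symmetry about its longitudinal axis is fully
determined by its radius profile r(x). From a binary half-silhouette the
profile is read per axial pixel column, and the volume is the sum of
unit-height cylinders, V = Σ π r(x)² Δx with Δx = 1 pixel, converted to µm³
by the cube of the µm/pixel scale.

Conventions that matter:

* **Radius.** The rotation axis lies on the pixel-edge boundary of radial
  index 0, so the radius of a column is (outermost foreground index + 1)
  pixel widths. This makes rectangles/cylinders exact and gives the
  rasterized half-disc a volume error that vanishes as the radius grows
  (measured: 0.8% at r = 100 px, < 0.1% at r = 400 px).
* **No smoothing.** Radii are taken as-is; Δx is fixed at one pixel.
* **Full silhouettes.** When the silhouette is not pre-bipartited, the
  midline is estimated per axial position as the mean of the two
  foreground extents, and the reported volume is the mean of the two
  half-revolutions (implemented by revolving the root-mean-square of the
  two half radii). A user-supplied axis coordinate overrides the estimate
  and is the faithful equivalent of manual bipartition.
* **Truncation.** An axial crop can be applied before extraction, e.g. to
  cut the cell at the level of the peristomial rim; the vaulted
  peristomial field is therefore never part of a cell volume.
* **Interior holes** are ignored (the profile is outline-based). For
  markedly non-convex sections this overestimates; an area-equivalent
  radius mode was considered and rejected as a default because outline
  reading matches how silhouettes are traced in practice.

Wall volumes are differences of revolved volumes (outer minus inner
profile). Axial positions where the inner radius exceeds the outer one are
physically impossible for a wall and are reported; a non-positive total is
an error. The identity wall + inner = outer holds exactly by construction.

Closed-form models are provided for dimension-based estimates; the
rotational ellipsoid V = (π/6)·L·W² is the standard choice for contracted
cells measured by maximum length and width. Note that volumes printed from
rounded mean dimensions can differ by a few µm³ from the formula applied to
the rounded values; no agreement beyond that is forced.

## Z-stack volumetry

Binary granule masks (slices × rows × columns) carry anisotropic voxel
dimensions: an in-plane µm/pixel value (required input) and a Z step
(default 0.5 µm, the typical optical-sectioning interval). Two routes:

* **Voxel counting**: foreground voxels × voxel volume. Exact on the
  digitized mask; serves as the independent oracle for the mesh route.
* **Surface meshing**: marching cubes at iso-level 0.5 on the 0/1 mask,
  padded with one background layer so every component closes, vertices
  scaled to µm before any measurement. The enclosed volume uses the
  divergence theorem (Σ faces of v₀·(v₁×v₂)/6), with the absolute value
  taken **per connected component**: disjoint granules always add, while a
  cavity nested inside a granule correctly reduces its volume. A
  non-watertight component is an error reporting the open-edge count —
  never silently repaired.

On a digitized sphere of radius 10 µm at 0.5 µm voxels, the voxel and mesh
routes land within 0.2% and 0.01% of the analytic volume respectively, and
their mutual agreement improves with radius.

**Portioning.** Two cuts along the cell's longitudinal axis (located at the
oral primordium, anterior towards low indices) split the mask into
anterior / middle / posterior portions. A voxel belongs to the interval
containing its centre coordinate; a centre exactly on a cut goes to the
more anterior interval. With the voxel method the portions sum to the total
exactly; with per-portion meshing the cut faces are re-triangulated, so the
sum may deviate slightly (≤ 2% on the synthetic granule fields used in
tests). The longitudinal axis defaults to the in-plane vertical ("y"),
matching cells imaged in ventral or dorsal view.

## Staging and LFM categories

Stage assignment is a total function on consistent oral-primordium states
(see the table in the package README); contradictory feature combinations
(e.g. a circular membranellar zone on two-rowed polykinetids) raise a
classification error naming the conflict. Without a primordium, auxiliary
descriptors (cell size class, macronuclear pattern) separate postdividers
from morphostatic specimens; absent those, MORPHOSTATIC is returned with a
low-confidence warning.

The four LFM categories (none / low / moderate / high) were originally
assigned by eye; this package bins the measured total volume instead.
Category 0 is reserved for exactly zero volume; the default cutoffs of
**2,000 and 8,000 µm³** are a calibration of this package chosen so that
the per-stage mean volumes 982 / 3,212 / 8,624 / 12,679 µm³ fall into
low / moderate / high / high — the dominant categories observed in those
stages. The cutoffs are configurable and echoed in every report. Because
LFM accumulation and primordium development are not fully synchronous,
volume-derived categories cannot reproduce every by-eye call and do not
claim to.

## Cohort statistics

* Stage summaries report n, arithmetic mean, min and max of total LFM;
  records without a measurement are skipped and counted.
* Stage increments take the early-divider mean as 0 (the onset of
  production); increment_i = mean_i − mean_{i−1} and its share of the
  final (VLD) mean. Unrounded increments sum to the final mean exactly and
  unrounded percentages to 100. Decreasing means only warn: production can
  pause while material is secreted or resorbed.
* Occupancy = 100 · LFM / cell volume, using the shape-function cell
  volume when both estimates exist.
* The swelling factor is deliberately conservative: minimum finished-wall
  volume over maximum intracellular LFM volume, a lower bound on the
  post-secretion expansion of the material.
* Wall summaries report the sample SD (n−1 denominator); the "M" of a
  published wall summary is interpreted here as the median, with the mean
  reported separately.
* Reporting rounds percentages to integers, folds to one decimal and
  volumes to integer µm³; raw doubles are always retained in machine
  output. No inferential statistics are computed.

## Synthetic generators

All generators are deterministic given a seed; changing the seed changes
realizations but never the ground-truth construction rules.

**Silhouettes.** Parametric rotationally symmetric profiles — rotational
ellipsoids and a champagne-flute lorica (spherical-cap aboral end, power-law
flaring bowl, constant radial wall thickness; defaults 175 µm length, 30 µm
opening radius, 8 µm aboral radius, flare exponent 2, 1.5 µm wall) — are
rasterized at a requested resolution (default 10 px/µm). Ground truth comes
from trapezoid integration of πr(z)² at 10× the raster resolution, plus
closed forms where they exist. The flute is a test fixture, deliberately
simple, not a morphometric model of any species.

**Granule stacks.** Non-overlapping spheres are placed by rejection
sampling inside a bounding cell ellipsoid (default 40 × 25 µm — a reduced
test-scale cell so default stacks stay around 50 × 160 × 100 voxels) with a
two-component radius mixture (defaults 1.0 and 2.5 µm, 40% large, echoing
the coexistence of smaller and larger granules). Spatial bias modes emulate
the observed distributions: uniform (early accumulation), a peripheral ring
at primordium level, and an anterior cluster (the pre-fission state, whose
ground-truth portions are (total, 0, 0)). The raster truth is the voxel
count per granule — exact by construction for the voxel route — with
analytic sphere volumes included for reference. Non-overlap keeps the total
a plain sum; an overlap-allowed mode computes union truth instead.

**Divider cohorts.** Per stage, total LFM is zero with a stage-specific
probability (1.0 for early dividers, 0.49 for early middle dividers — about
half of which carry a low quantity — and 0 later) and otherwise a
mean-matched lognormal draw. Lognormal because volumes are positive and
strongly right-skewed (a 5.3-fold spread among only five very late
dividers). The log-scale dispersions are fitted to the published
within-stage spreads at the published sample sizes: σ = 0.065 (EMD) and
0.39 (LMD) reproduce the reported maxima in expectation, σ = 0.717 (VLD)
the 5.3-fold range at n = 5. For ELD, the 2.4-fold-implied σ ≈ 0.42 would
put the lognormal median below the 8,000 µm³ category cutoff and make
"moderate" the modal ELD category, contradicting the observed dominance of
high quantities; σ_ELD = 0.30 is used instead (expected fold ≈ 1.9),
prioritising a faithful category composition over the fold range, which is
anyway asserted from the published extreme values directly. Cell dimensions
are drawn around the per-stage means (72×61 to 104×73 µm, 5% CV) and cell
volumes use the ellipsoid model — generated cells *are* rotational
ellipsoids, so the shape-function volume equals the ellipsoid volume for
them. The anterior/middle/posterior split of each specimen's LFM follows
fixed stage-typical fractions encoding translocation into the proter
(ending at 90/10/0% in very late dividers).

What the generators do **not** emulate: staining variability, out-of-focus
light and point-spread blur, segmentation error, non-spherical or internally
structured granules, lorica agglutination, and any correlation between cell
size and LFM content. Passing tests therefore demonstrate correctness of
the volumetric and statistical machinery on idealized inputs, not
robustness to real-image segmentation noise — binary masks are this
package's input contract.

## Problem sizes and numerical tolerances

The test suite and the acceptance script use: half-discs up to r = 400 px;
digitized spheres of 5–10 µm radius at 0.5 µm voxels; granule fields of
~60 granules in the 40 × 25 µm test cell; and cohorts of 1,000 specimens
per stage for distributional recoveries (sampling error of the stage mean
≈ 2% at the largest dispersion, against a 5% assertion band). Recovery
tolerances: shape-function volumes within 2% of ground truth at ≥ 10 px/µm;
voxel volumes exact against voxelized truth; mesh volumes within 3% on
spheres of r ≥ 5 µm and within 5% on granule fields (small granules are
only a few voxels across, where the inscribed-surface bias is largest).

## Known limitations

* The shape function assumes rotational symmetry; bilaterally compressed
  cells violate it and the two-half average only partly compensates.
* Mesh volumes systematically sit slightly below voxel volumes for convex
  bodies (marching cubes inscribes the voxel surface); the difference is
  part of the documented 3% band.
* The zero-inflated lognormal is a modelling choice; the true within-stage
  LFM distribution is unknown (published n per stage is 3–5).
* Category cutoffs are a volume-based surrogate for by-eye classification
  and inherit its irreproducibility at the class boundaries.
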