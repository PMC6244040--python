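# Methods

This note records the models, conventions and numerical choices behind
`uavtraits`, and what the synthetic scenes do and do not establish about
real imagery.

## Raster model and geometry

A raster is a rectangular grid with a cell size in cm/pixel and a world
origin at the top-left corner of pixel (0, 0); world coordinates are metres
with y increasing downward (image convention).  Missing data is NaN.  A
pixel belongs to a region of interest iff its **center** lies strictly
inside the polygon — boundary centers are outside.  This single rule makes
masks bit-reproducible and makes canopy cover an exact pixel-counting
quantity.

Plot polygons carry genotype and genetic-background labels (GRP1–4: low
stalk stiffness, high stalk stiffness, long growing period, mixed).  The
analysis region of every plot is the polygon shrunk inward by 0.25 m
(mitred buffer), because leaves of adjacent plots interpenetrate late in
the season; the shrink distance is configurable per plot.

## Plant height

CSM = DSM − DEM, in cm, so heights are positive above ground.  Plant pixels
are selected by NGRDI > 0 (strict; 0 classifies as soil, since bare-soil
NGRDI is non-positive), and canopy cover uses NDVI > 0.1 (strict at the
threshold) — both conventions chosen so that the boundary value is
non-plant.

The representative plot height is computed in three steps:

1. **Block maxima.** The plant-masked CSM inside the shrunk ROI is
   aggregated to `resample_cell` (default 5 cm — the native synthetic
   resolution is 2 cm, and the resample factor controls how many points
   feed the interpolation) with **max** aggregation, then tiled into
   non-overlapping `window`×`window` blocks (default 3).  Each block with
   at least one valid pixel emits the world coordinates and value of its
   maximum native pixel, so every emitted height is literally a CSM cell
   value at that location.  Partial edge blocks are kept — small ROIs
   would otherwise lose coverage.  Mean aggregation is deliberately not
   offered: it would re-introduce the low-leaf dilution the block-maxima
   construction exists to avoid.
2. **Ordinary kriging.** A spherical variogram with zero nugget is fitted
   to the binned empirical semivariogram by bounded least squares; if the
   fit fails (too few lag bins, degenerate optimum) a linear model through
   the origin is used, and a constant field short-circuits to its value.
   Zero nugget keeps kriging an exact interpolator, which yields the
   invariant the tests assert: the surface maximum is never below the
   largest observed canopy maximum.  Coincident points are collapsed to
   the larger value before solving (they are canopy *maxima*).
3. **Surface maximum.** The surface is evaluated on a grid over the shrunk
   ROI at `grid_cell` (default 10 cm) *plus* the data locations themselves,
   and the maximum is the plot PH.  With fewer than 5 points no variogram
   is fittable and max(z) is returned directly.

Plots with no plant pixels produce a missing-value record with status
`"no-plant"`, never an exception from the batch path.

## Canopy cover, NDVI, growth traits

CC is the plant-pixel count over the ROI pixel count (NaN reflectance
pixels count as non-plant); plot NDVI is the arithmetic mean of NDVI over
plant pixels.  AGRPH and CRPH are straight finite differences over the
stage calendar (defaults S1–S4 at 24/44/57/84 days after sowing); an
interval with a missing endpoint is NaN, and CRPH requires a positive
final-stage height.  AGRPH is invariant to shifting all dates; CRPH to
rescaling heights.

**Outlier plots.**  The lodging rule flags any plot whose height series
strictly decreases between some pair of consecutive stages and strictly
increases between a later pair; the low-emergence rule flags canopy cover
below 0.05 (absolute) at the second stage.  Both thresholds are declared
package defaults, configurable via `OutlierRules`; every removal is logged
with its rule and values.

## Descriptive statistics

The CV rule is conditional on the Shapiro–Wilk test: p > 0.05 keeps the
mean in the denominator, p ≤ 0.05 (normality rejected, boundary included)
switches to the median.  Skewness is the adjusted Fisher–Pearson sample
skewness and kurtosis is bias-corrected excess kurtosis, so large normal
samples report values near 0/0; quartiles use linear interpolation.  These
conventions are declared, not uniquely implied by the quantities they
mirror.  Group differences use the one-way F across GRP1–4 per stage, with
stages reported sorted ascending by F.

## Shape clustering

Series are z-normalized (constant series map to the zero vector, flagged by
construction: their SBD to anything non-constant is 1).  SBD enumerates all
2T−1 zero-padded shifts — for the 4-stage series here, all 7 — via the full
cross-correlation; no shift-range truncation is applied.  The shape
extraction centroid is the principal eigenvector of Q AᵀA Q (A the members
aligned to the current centroid, Q the centering projector), z-normalized,
with the eigenvector's sign chosen to maximize summed similarity to the
members.

k-Shape alternates assignment and extraction until labels stabilize
(max 100 iterations), repairing an emptied cluster by reseeding it with the
row farthest from its centroid.  Because length-4 series admit several
near-equivalent shift alignments, a single random start can settle on a
shifted, distorted centroid; the implementation therefore restarts from
`n_init = 5` seeded initial partitions and keeps the run with the smallest
within-cluster SBD sum.  All randomness flows from one integer seed, so
results are reproducible; the per-iteration refinement is non-increasing in
the objective given fixed centroids, and the tests assert the weaker, always
true property that the returned partition is no worse than its seeded start.

Validity indices use SBD throughout: DBI with centroid-to-member scatter
and centroid separation, Dunn as minimum between-cluster distance over
maximum within-cluster diameter.  `select_cluster_number` scans k = 2 up
to `k_max` (default 20, truncated with a warning beyond the row count); a k
that simultaneously minimizes DBI and maximizes DI wins outright, otherwise
the smallest rank-sum (DBI ascending + DI descending) decides, ties to the
smaller k — the joint criterion is a stated goal, not an algorithm, so the
fallback is an explicit design choice.

## Typical curves and naming

A cluster's typical curve is the per-stage member mean with a 95%
t-interval half-width t₀.₉₇₅,ₙ₋₁·sd/√n (small clusters are the norm, hence
the t rather than normal quantile).  Naming uses the zenith (argmax of the
means, ties to the earliest stage) and its neighbour on the longer arm,
classified against the chord from the zenith to that arm's endpoint:
Z1→(adjacent S2, endpoint P4), Z2→(S3, P4), Z3→(S2, P1), Z4→(S3, P1).  The
"on the chord" band is ±2% of the curve's value range (configurable);
with a relative band the name is invariant to positive affine transforms
of the values.  The Z1 arm assignment never occurs for monotone-peaked
growth traits and is an extension for completeness.

Recognition rate is the share of a scope's members carrying its most
frequent group label, where a scope is a cluster or all clusters pooled by
name type.  Membership overlap between two clusters is
100·|A∩B|/min(|A|,|B|) — the min denominator is a declared choice; the
quantity is symmetric and reaches 100 for nested sets.

## Synthetic scenes

The generator emulates the trial layout the pipeline targets: plots of
2.4 m × 2.0 m sown at 6 plants/m² in rows 0.6 m apart, separated by 0.4 m
alleys, over a smooth DEM with 2 cm of low-frequency relief (flat terrain,
but nonzero so CSM differencing is exercised).  Each plant is a truncated
paraboloid crown h(r) = H·max(0, 1 − (r/R)²) with R = 0.4 m; per-stage apex
ranges default to 5–26 / 69–184 / 117–251 / 148–365 cm across the four
stages (spanning the spread a maize trial shows from jointing to maturity),
with a per-plot vigor anchor and 2 cm per-plant jitter.  Plant centers are
snapped to pixel centers so the rendered canopy maximum equals the drawn
apex exactly, making the truth table a construction oracle.  Reflectances
(plant green/red/nir 0.12/0.06/0.45; soil 0.10/0.12/0.14) separate plant
from soil under both index rules with margin, and configurations violating
separability are rejected at construction.

What the scenes do **not** emulate: photogrammetric reconstruction noise,
mixed plant/soil pixels at crown edges (reflectance is uniform per class),
radiometric miscalibration, tassel geometry, lodging geometry, or
inter-plot leaf crossing.  Passing the recovery suites therefore certifies
the *algorithmic* chain — masking, block maxima, kriging, clustering —
under the stated canopy model, not sensor-level robustness.  The trait
time-series generator plants prototype curves plus i.i.d. Gaussian noise
with per-cluster group mixtures, giving known labels for the clustering and
recognition-rate suites.

## Problem sizes

The test suite runs scenes of up to 56 plots at 2 cm/pixel (single stage)
for the plant-height recovery statistics, 90-series matrices for clustering
recovery, and k-scans to k_max = 8 on 80 series; these sizes give stable
statistics for the properties asserted while keeping the default suite
around ten seconds on one CPU.

## Known limitations

* Ordinary kriging can overshoot between points (it is exact *at* them), so
  the surface maximum can slightly exceed the tallest observed maximum;
  on the synthetic scenes this stays well inside the 5% recovery band.
* With four samples per series, SBD's zero-padded shifts discard most of
  the overlap; shift-0 alignment dominates in practice, and the restart
  strategy exists precisely because the shift landscape is coarse.
* The Shapiro–Wilk p-value is approximate above n = 5000 (the underlying
  implementation warns); the CV gate is insensitive to this at the sample
  sizes the pipeline produces.
* TIFF output stores the grid transform in the image description tag; GIS
  geokeys are not written, so downstream GIS use needs a world-file or
  reprojection step.
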