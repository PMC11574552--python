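# Methods

## Scope and data model

The package analyses 2-D maximum-projection tiles of roots growing in
transparent soil, already segmented into five per-pixel classes (soil
particle, pore space, mobile bacteria MB, root biofilm RB, particle biofilm
PB) by an external trainable classifier. The classifier itself is out of
scope: the pipeline starts at its exported class-probability stacks and
assigns each pixel its maximum-probability class, breaking ties by the
fixed order PARTICLE < PORE < MB < RB < PB. The manually traced root
(centreline polyline ordered from the tip, closed boundary polygon)
overrides classifier output inside the boundary. All coordinates are µm;
pixel (0, 0) is top-left with centers at (i + 0.5)·pixel size; the default
resolution is 6.21 µm/px on 3.2×3.2 mm tiles.

## Patch extraction

Each bacterial class mask is decomposed into compact regions by watershed:
seeds are the true regional maxima of the Euclidean distance transform of
the mask (plateaus adjacent to higher values are not maxima), merged when
closer than 3 px, and flooding runs on the negated distance transform.
This splits merged blobs at their necks while passing single convex blobs
through unchanged, and the regions always partition the mask exactly.
Regions below 4 px are discarded as sub-resolution noise (configurable).
Per region the pipeline records the area A (pixel count × pixel area), the
mean image intensity I, the unweighted pixel-center centroid, and the
covariates at the centroid:

- dp, dr: the Euclidean distance transforms of the particle-mask and
  root-mask complements sampled at the centroid's pixel (zero on or inside
  the mask);
- da: the arc length of the nearest vertex of the centreline resampled to
  1-px spacing — distance from the root tip *along the root*, which is the
  natural axis for colonization profiles. Evaluating covariates at the
  centroid (one vector per patch) treats a patch as a point object; for
  patches large relative to their distance gradients this is a deliberate
  simplification.

## Occupancy density model

The density of bacterial presence over any subset of (dp, dr, da) is a
weighted Parzen-window estimate: each patch spreads its fluorescence weight
A·I/M (M = Σ A·I) uniformly over an ellipsoid of isotropic radius
h = √(A/π) — the radius of a disc of the patch's area — and the kernel is
normalized to unit integral by C = 1/(Vₙ Π hⱼ) with Vₙ the n-ball volume.
A patch's weight, not its count, is what matters: dense or bright patches
contribute proportionally more, so p̃ estimates where a randomly chosen
*cell* sits, not where a randomly chosen patch sits.

Numerical choices:

- Bandwidth floor: h ≥ one pixel-equivalent (6.21 µm by default) so no
  kernel has near-zero measure.
- Evaluation: the field is evaluated at grid-cell centers. A top-hat kernel
  narrower than a grid cell can cover no cell center; such kernels (and any
  kernel that happens to cover no center) deposit their whole weight into
  the cell containing them instead, so mass is conserved up to genuine
  grid truncation. On grids fine relative to the bandwidths this reduces to
  plain center evaluation; on coarse grids (e.g. 500 µm da bins) it reduces
  to a weighted histogram, which is the correct limit.
- Boundary truncation: kernels overhanging the attainable region (dp < 0,
  or beyond the grid) are *not* renormalized; the Riemann-sum deficit is
  reported as the field's `coverage` metadata.
- Accumulation order is canonicalized by sorting patches, so the field is
  bit-identical under any permutation of the input table.
- Default grids: dp, dr ∈ [0, 500] µm at 10 µm bins; da ∈ [0, 10] mm at
  0.5 mm bins. Configurable via `GridSpec`.

The null model feeds every pixel of a support class (pore space by
default) through the same estimator with area = pixel area, intensity = 1
and bandwidth = pixel radius √(pixel area/π): the density expected if all
of that space were equally probable. An optional seeded subsampling of
support pixels bounds the cost on large mosaics. The temporal extension
fits one independently normalized field per timepoint on a shared grid;
empty timepoints yield zero fields flagged as such.

Cell-density scaling: ρ(x) = p̃(x)·Q̄ with Q̄ the total calibrated cell
count divided by the number of roots R. The calibration is a straight line
fitted by OLS (total pixel intensity = slope·cells + intercept; package
default slope 39, intercept 331). Inverting it for a patch uses the
patch's total intensity I·A/pixel-area, treats the intercept as per-patch
background, and clamps at zero — so splitting one true patch into k
recovered fragments undercounts by (k−1)·intercept/slope cells, a ~2%
effect at typical patch sizes.

## Colonization statistics

- State per root×timepoint from the patch-class multiset: NONE,
  MOBILE_ONLY, MOBILE_AND_BIOFILM, or BIOFILM_ONLY (the fourth state is
  kept distinct for completeness; cohort tables can collapse it into
  MOBILE_AND_BIOFILM for a three-category presentation).
- Profiles: per class and timepoint, calibrated cells summed into
  distance-from-tip bins and divided by (bin width × R) — CFU mm⁻¹ of
  root, averaged over the cohort. Bins beyond every supplied root length
  are masked.
- Minimum biofilm–tip distance: min over RB patches of da per
  root×timepoint; the cohort summary is the mean ± SD of those minima.
- Timepoint comparison: two-sided Mann–Whitney U of the last timepoint's
  minima against all earlier ones pooled, exact null when both groups have
  ≤ 20 observations, normal approximation otherwise. The rank test was
  chosen because group sizes are small and no normality is established;
  Welch's t is available behind a flag. The exact method does not apply a
  tie correction; tip distances are continuous so ties have measure zero.

## Synthetic microcosm generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline's recovery properties are verified.

- Cohort layout mirrors the target dataset: 12 roots × 4 timepoints (12,
  24, 36, 48 h), each root a vertical column of 2–6 tiles imaged from the
  tip; soil and root are generated once per root on the whole column and
  cropped into tiles.
- Particles: non-overlapping discs, diameters uniform on 250–1250 µm,
  placed by rejection sampling until the target packing fraction (default
  0.5) or an attempt cap (50× the expected disc count) is reached, with a
  warning and the achieved fraction reported if capped. The 0.5 default
  reflects that the analysed images are projections through ~228 µm of
  granular medium, whose projected particle coverage is well above a
  sparse single layer. Disc shape is a simplification — particle shape
  enters no downstream formula.
- Root: a gently sinusoidal centreline entering from the top edge, tip
  inside the bottom (tile-0) tile, buffered to the root width (default
  300 µm) with a round cap; the mask is the polygon rasterized at pixel
  centers — the same rule the segmentation stage uses, so the two agree
  exactly. Roots are static across timepoints: growth is not simulated,
  and the temporal structure lives entirely in patch placement.
- Patch placement laws (per class, iid draws from the law's support):
  - MB: pore pixels with probability ∝ exp(−dr/λ_r)·exp(−dp/λ_p),
    λ_r = λ_p = 100 µm, concentrating ~all mass within 200 µm of the root
    or a particle surface; at 12 and 24 h an extra exp(−da/λ_a) tip bias
    (λ_a = 1.5 and 2.5 mm) plants the early near-tip peak of mobile
    activity, absent later when mobile bacteria spread along the root.
  - RB: uniform on root-surface pixels at da ≥ d_min(t), the biofilm-free
    tip zone, d_min = 794.26 µm growing by 20 µm/h after 12 h — a planted
    (not mechanistic) emulation of the tip zone lengthening with time.
  - PB: uniform on particle-perimeter pixels within 100 µm of the root,
    falling back to the whole perimeter (with a warning) if that set is
    empty.
  - Counts per tile are Poisson with class-specific temporal weights (MB
    peaking at 12–24 h, RB/PB increasing to 48 h); patch areas and
    cells-per-patch are lognormal. No quantitative patch-size or
    cells-per-patch distributions are established for this system; these
    are free generator parameters, chosen to give patches of tens to
    hundreds of pixels.
  - Cross-class exclusion: candidate centroids keep a margin of twice the
    two patch radii from patches of other classes, and painting caps each
    region at twice its nominal radius, so rendered ground truth is
    guaranteed unambiguous; a genuinely conflicting planted table raises.
- Rendering: each patch is painted as the compact set of its-area-many
  nearest free pore pixels; the region's summed intensity equals the
  calibration line's prediction for its cell count exactly (integerized)
  before optional background and Gaussian noise. The probability stack is
  one-hot from the ground-truth labels (root presented as pore, since a
  classifier never sees the manual trace) with optional label-flip noise.
- Determinism: every stage draws from a named substream of one master
  seed, so scenes are bit-identical under a fixed (config, seed) and
  stages can be regenerated independently.

What the generator does *not* emulate: optical point-spread and depth
attenuation, classifier-correlated segmentation errors (label flips are
iid), irregular particle shapes, root growth, and bacterial motility or
population dynamics. Passing recovery tests therefore demonstrate the
correctness of the analysis machinery under known truth, not the accuracy
of any upstream classifier on real images.

## Problem sizes used in the shipped checks

The test suite exercises full-size single tiles (515×515 px) for
round-trip, null-model and parameter-recovery properties (λ_r recovered
within 20% from 500 planted MB patches; planted cell totals within 5% on
noiseless scenes), and runs the default 12-root cohort end-to-end through
the command-line pipeline. The acceptance script integrates the 3-D kernel
at 0.1 µm midpoint resolution and normalizes a 50-patch field on a 2 µm
grid; both are exact-to-quadrature checks of the estimator's normalization.

## Known limitations

- Covariates are point evaluations at patch centroids; large patches near
  steep distance gradients are summarized coarsely.
- The calibration intercept is treated as per-patch background when
  inverting intensities, which biases counts down slightly when the
  watershed over-splits.
- The exact Mann–Whitney null ignores ties (irrelevant for continuous
  distances, relevant if distances are heavily rounded).
- da is defined by the nearest resampled centreline vertex, which for
  points far to the side of a strongly curved root can differ from the
  true foot-of-perpendicular arc length by up to the local curvature
  scale.
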