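# Methods

This note documents the measurement model, conventions, parameter
defaults and design choices of `diamorph`, and what the synthetic
phantoms do and do not establish about real data.

## Coordinate and angular conventions

Voxel arrays are `[z, y, x]`; physical points `(x, y, z)` in mm.  After
positioning, Z is the shaft axis with the proximal landmark at lower Z,
X is medio-lateral, Y dorso-plantar.  Rays and neutral axes are indexed
by degrees counter-clockwise from +X (the medial reference), viewed from
the proximal end: 0° medial, 90° dorsal, 180° lateral, 270° plantar.
Map matrices have rows 1..17 proximal→distal and columns 0..359; rendered
images put section 1 at the bottom.

## Positioning protocol

1. **Axis alignment** — the minimal rigid rotation carrying the
   proximal→distal landmark direction onto +Z, applied in a single
   reslice onto an isotropic grid at the finest input spacing.  Binary
   masks are resampled nearest-neighbour; grayscale data are resampled
   linearly and re-thresholded at 0.5 (avoids fractional labels).  A
   volume already aligned on an isotropic grid passes through untouched.
2. **Roll fixing** — rotation about Z until the roll-reference
   direction (roll-reference landmark minus shaft axis, projected to
   XY) parallels +Y.  A reference on the axis is rejected.  On phantoms
   the roll-reference landmark replaces the visual articular-surface cue
   used on real bones, which has no analogue on a tube.
3. **Mirroring** — right-sided elements are reflected across the mid-X
   plane after alignment (X is the medio-lateral axis), converting them
   to left antimere form; mirroring is an involution.

Mechanical length L is the Z distance between the two landmarks after
alignment.

## Sections and contour cleaning

Seventeen sections are taken at 25% + 2.5%·k of L (k = 0..16), each a
single-voxel plane at the nearest resliced Z level (no slab averaging),
resampled to exactly 0.1 mm pixels (nearest-neighbour), reduced to the
largest connected component (stray specks warn), hole-filled, and
boundary-cleaned:

- **Hole filling** distinguishes the medullary canal from intracortical
  pores by flood labelling the enclosed background cavities: the largest
  enclosed cavity is the canal and stays open, all others are filled.
  Limitation: a pore larger than the canal would be misidentified
  (not a realistic cortical geometry).
- **Boundary smoothing** computes a bivariate-normal (Gaussian) local
  occupancy field (default bandwidth 0.2 mm = 2 px, configurable — the
  value is a package default, not an inherited constant) and re-decides
  only the one-pixel boundary layer with a symmetric ≥ 0.5
  include/exclude rule.  Interior pixels are never removed; the
  bandwidth → 0 limit is the identity.

## Radial measurement

Rays are cast from the **cortex-only area centroid** (canal excluded;
the alternative filled-section centroid is equally defensible but
cortex-only is the standard cross-sectional-geometry choice).  The mask
is converted to a Gaussian local-occupancy field (sd 1 px) and sampled
bilinearly at 0.25-px steps along each ray; boundary positions are the
0.5 occupancy crossings with linear sub-step refinement.  Sampling the
occupancy field rather than the raw binary mask localizes boundaries
with sub-voxel precision (quantization from voxelization and reslicing
averages out); the curvature bias of the 1-px averaging, ~σ²/(2R), is
below 0.01 px at the radii of interest.  The outermost crossing is the
periosteal border and the innermost the endosteal border (intermediate
crossings of a non-convex cortex are ignored); if the centroid lies in
cortex, the endosteal radius is 0 on rays without an inner border.

SMA uses raw pixel moments about the centroid with the per-pixel self
moment a⁴/12 (consistency with the continuum formula at coarse grids)
and the axis-rotation identity; values are computed for 0..179° and
tiled, making the 180° redundancy exact by construction.  The neutral
axis *at* angle θ runs along direction θ, so I(0) resists bending about
the medio-lateral axis; this fixes the phase so that ray index equals
axis angle.

## Standardization and group maps

sCBT = t/L (dimensionless); sSMA = I/(M·L) (mm³/kg).  M is by default
the mean body mass of the individual's (group, sex) cell — matching the
use of sex-specific species means — with a pass-through for direct
individual masses and a femoral-head-diameter path that requires
user-supplied sex-specific linear coefficients (none are bundled).
Consensus maps are pixelwise means; CV maps pixelwise sd/mean with the
n−1 denominator (small samples).  Colour anchors: one global (min, max)
across group consensus maps for between-group comparison, per-group
anchors for within-group comparison, global anchors across CV maps.
Display upsampling is bicubic on a column-periodic grid (no 0°/360°
seam) and never alters the 17×360 data; degenerate anchors render a
uniform mid-colour with a warning.

## Summary statistics

Per-individual values at a section level are means over the 360 rays;
groups are compared by one-way ANOVA and the Student–Newman–Keuls
stepwise range test (studentized-range quantiles from scipy;
α = 0.05 default; harmonic-mean allowance for unequal n; a
non-significant range blocks nested ranges).  Sexes are pooled.

## Penalized discriminant analysis

Maps are flattened to n×6120 (raster order: section, then degree).  PDA
is realized as **penalized optimal scoring**: regress class indicators
on the centered design with per-sample-averaged squared error and
penalty λ·βᵀΩβ, Ω = LᵀL for the combinatorial Laplacian of the 17×360
cylinder grid (periodic in degrees, free at the ends; constants span the
null space).  The optimal-scoring eigenproblem yields up to K−1
discriminants, ordered by canonical eigenvalue, scaled to unit pooled
within-class sd, with deterministic sign (last class centroid not below
the first).  Classification is nearest group centroid in discriminant
space, ties broken toward the first class in sorted order.

Numerics: all fits go through the n×n Gram matrix G = X_c A⁻¹ X_cᵀ with
A = λΩ + εI and ε = 10⁻⁸ · mean column energy (invertibility ridge;
λ = ε = 0 with p > n is rejected with a message to use λ > 0).  For the
cylinder penalty, A⁻¹ is applied spectrally — DCT-II along sections and
real FFT along degrees diagonalize the grid Laplacian — so a fit costs
O(n·p log p); arbitrary sparse penalties use a sparse LU factorization.
The per-sample loss convention (effective penalty n·λ·Ω) makes the fit
invariant to duplicating observations and keeps λ comparable across
fold sizes.

Effective degrees of freedom: df(λ) = trace[X_c (X_cᵀX_c + n(λΩ+εI))⁻¹
X_cᵀ] = Σ g/(n+g) over eigenvalues g of the centered Gram — continuous,
monotone non-increasing, df(0⁺) ≤ min(n−1, p), df(∞) → dim null(Ω) = 1.

**λ selection**: 12 per group train (test = remainder); 100 repeats of
stratified 12-fold CV (each fold one member per group; fold draws are
shared across the λ grid so comparisons are paired).  The 25-point log
grid is auto-scaled: initial scale ‖X_c‖²/tr(Ω), bounds expanded by
decades until df sweeps from ≈ min(n−1, p) down to ≤ 2.  The 95% band is
mean ± t₀.₉₇₅,R₋₁ · sd across repeat means; λ is **admissible** when its
mean error ≤ the minimum upper band (non-strict, so a perfectly
separable design — all errors zero — keeps its admissible set), and the
admissible λ with the lowest df is selected.  One seed governs split,
folds and repeats; everything is reproducible from it.

Loading maps reshape a discriminant to 17×360; a positive pixel means a
larger property value there raises the score on that discriminant, and
the sign-change boundary is extracted for display.

## The phantom generator

A phantom is a tube along Z: outer radius R(φ, f) and wall w(φ, f) are
arbitrary numpy-vectorized functions of angle and length fraction.
Voxelization is a center-of-voxel membership test (binary, no
anti-aliasing, matching segmented renderings).  Validity requires
w > 0, w < R and voxel ≤ min(w)/2 (two voxels across the thinnest wall).

**Analytic truth** is evaluated before voxelization on the 17×360 grid:
area/moment integrals by 14 400-point periodic trapezoid quadrature
(effectively spectral for smooth contours); SMA about the analytic
centroid.  Truth *thickness* is ray-cast from the analytic centroid
against 1440-gon contours — the measurement defines thickness along
centroid rays, and for asymmetric walls the centroid is offset from the
tube axis, so the raw wall function is not the estimated quantity (it is
retained as `truth["wall"]`).

**Default cohort** (the package's standing validation conditions,
43 = 14 + 14 + 15): group A, chimpanzee-like — wall 2.3 mm, mildly
elliptical 5.8/5.4 mm, 45 kg; group B, gorilla-like — wall 2.2 mm,
6.4/6.0 mm, 120 kg, plus a planted plantar-proximal thickening
(+1.2 mm Gaussian bump at 270°, 30% length, σ = 30°/8%); group C,
human-like — wall 1.4 mm, dorsoplantarly elongated 5.2/6.8 mm, 65 kg.
Length 60 mm (2.5% ≈ 1.5 mm between sections), gentle taper, voxel
0.3 mm, smooth surface noise 0.02 mm.  Between-individual jitter:
lognormal wall scale (CV 0.08), lognormal size scale (CV 0.05), angular
phase jitter (sd 2°), lognormal length (CV 0.04) and mass (CV 0.08)
jitter, ~1/3 right-sided (stored mirrored), roll offsets uniform in
[0°, 360°).  Multiplicative jitters truncate the underlying normal at
2.5 sd so no draw can violate the sampling-adequacy invariant (verified
minimum wall 0.72 mm over 200 seeds versus the 0.6 mm bound).

A **CV band** at 180° (σ = 20°) multiplies every individual's wall by
exp(ε·g(φ)), ε ~ N(0, 0.20) truncated: a planted region of elevated
between-individual variability.  The amplitude is set so the planted CV
clearly exceeds the discretization-noise CV floor of the thin-walled
group at 0.3 mm voxels (~0.08–0.11); below that floor, hot-spot
localization would measure measurement noise, not the planted signal.
The hot-spot locator (`maps.cv_hotspot_deg`) smooths the
section-averaged angular CV profile with a 21° circular window (the
band scale) before taking the peak.

A separate **two-group band cohort** (`band_contrast_cohort`) plants a
+0.5 mm thickness band covering half the circumference; it validates
that the first discriminant's positive-loading region localizes a known
contrast (IoU with the planted region).  A sign-based region is only a
meaningful localization readout when the planted contrast is comparable
in extent to half the map, which is why this check uses its own cohort
rather than the three-group default.

**What the phantoms do not emulate**: trabecular bone, metaphyses,
diaphyseal curvature, scanner physics (noise spectra, beam hardening,
partial-volume gray levels), segmentation error, and real within-species
covariance structure (the jitter model is simple and stationary apart
from the planted band).  Passing the phantom suite shows the *pipeline*
is correct and sensitive at realistic geometry and resolution; it does
not by itself validate biological conclusions drawn from real scans.

## Problem sizes and determinism

The standing validation conditions use 0.3 mm voxels for the 43-phantom
cohort (measurement ≈ 1 s/individual) and 0.1 mm voxels for
single-phantom truth-recovery checks; PDA selection evaluates a
25-point λ grid under 100×12-fold CV via the spectral Gram path.  A full
pipeline run completes in about a minute on one CPU.  Every stochastic
step (cohort draws, split, folds, repeats) derives from a single seed;
reruns are byte-identical.

## Known limitations

- Nearest-neighbour reslicing adds up to ~0.5 voxel boundary error per
  rotation; worst-case pixel errors after the full protocol approach
  ~1.4 voxels.  Sub-voxel accuracy relies on the occupancy-field
  boundary estimator described above.
- `fill_holes` assumes the canal is the largest enclosed cavity.
- The SNK step-down procedure reports ordered significant pairs only;
  it does not produce adjusted p-values.
- The femoral-head body-mass path ships no regression coefficients;
  they are population-specific and must be supplied.
- With K groups only K−1 discriminants exist; loading-map localization
  of *which* planted difference drives which discriminant is only
  unambiguous in two-group designs.
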