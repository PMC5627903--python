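# Methods

## The measurement problem

Calcein AM is cleaved by intracellular esterases to fluorescent calcein, so
only metabolically active cells with intact membranes light up. On a stained
DMEK graft imaged in situ, three tissue classes appear: viable endothelium
(bright, usually with a brighter nucleus), attached dead cells (dim — only
marginally above bare membrane), and bare Descemet membrane where cells have
been scraped off (near black). `endoquant` quantifies such images; because
no public image sets exist for the assay, a synthetic generator with exact
ground truth provides the validation substrate.

## Synthetic endothelial mosaics

**Geometry.** A graft is a disc of diameter `graft_diameter_mm` (default
8 mm, the clinical trephine) populated with
`N = round(density · π r²)` cells. Sites are sampled uniformly in the disc
and relaxed toward a centroidal Voronoi tessellation by Lloyd iteration
(`regularity` iterations, default 10 — enough to reach the quasi-hexagonal
regularity of healthy endothelium; 0 gives a Poisson mosaic). Sites within
three mean spacings of the rim are mirrored across the circle so edge cells
close at the boundary; final boundary-crossing polygons are clipped exactly
to the disc. The achieved density is exact by construction (N/area);
generation refuses degenerate configurations below 50 cells. Each nucleus
sits at its cell centroid jittered by up to 15% of the equivalent cell
radius, with radius 0.27× the cell radius. Every stochastic operation takes
an explicit seed; identical spec+seed is byte-identical.

**Damage.** Primitives — peripheral rim, incarceration wedge, parallel
ejection streaks, polygonal patches, tears (buffered polylines), a
triangular orientation mark — are shapely footprints clipped to the disc. A
cell whose centroid falls inside a footprint switches to the primitive's
mode: `bare_dm` (cell absent) or `dead_attached` (cell present, dead).
Primitives compose in order; footprints are retained for damage attribution.
The standard non-viable periphery used by the benchmarks is a 400-µm rim
whose outer half is bare membrane and whose inner half is attached dead
cells, mirroring the appearance of bare cores surrounded by
ethidium-positive cells at real graft edges. `calibrate_streak_width`
bisects the streak band width (cell capture is monotone in width) to hit a
requested true viable-area fraction within ±0.005.

**Truth bookkeeping.** The true viable-area fraction is viable polygon area
over total tessellated area; the tessellation covers the disc to <0.5%, and
the polygon-based fraction agrees with pixel rasterization (nearest-site
ownership of pixel centers) to within 1% — both directions are tested.

## Photometric render model

Region means on the 8-bit grey scale: cytoplasm 100, nucleus 130 (nuclear
staining exceeds cytoplasmic at the working dose), attached dead cells at
`bare_dm_mean + 3` ("only marginally higher" than bare membrane), background
outside the disc 0. A Gaussian PSF (default σ 1.2 px at the 5-µm/px global
view, where single cells are unresolved) blurs the piecewise-constant scene;
zero-mean Gaussian read noise is added **after** the blur, so a structurally
uniform patch has pixel SD exactly `noise_sigma`; the result is clipped to
[0, 255] and quantized to uint8. Poisson shot noise is not modelled (no
photon-count information is available for the source imaging system).
A fraction `undetectable_nucleus_fraction` (default 0.075) of viable cells
renders without nuclear contrast: this is the mechanism by which
calcein-based counting under-counts (see Agreement below). Optional
channels: a nuclear counterstain (all attached cells' nuclei) and a
dead-cell channel (dead-attached nuclei), rendered with the same PSF/noise.

**Calibration.** `calibrate_render(target_contrast, target_snr)` fixes the
two free parameters. Because noise is post-blur and independent,
viable-patch variance decomposes exactly as structural variance
(nucleus/cytoplasm texture, measured on a noise-free reference render) plus
`noise_sigma²`, so the SNR target yields `noise_sigma` in closed form. The
peripheral patch mean is affected by zero-clipping of the noise and by
quantization, so `bare_dm_mean` is refined by a short fixed-point iteration
against rendered rim patches (the iteration map has slope in (0,1], hence
converges monotonically). Calibration patches are drawn by the same seeded
sampling rule as downstream photometry — non-overlapping 25×25 arrays fully
inside their region — and the returned spec must pass a rendered self-check
within 5% or calibration raises. Default targets are the published contrast
15.41 and SNR 14.27.

**Kinetics.** Relative intensity = slope·dose · rise(t) · exp(−k·(t−2 h))
for t past the 2-h peak, rise linear before it. The decay constants are
module constants derived from the printed endpoint pairs: 37 °C organ
culture k = ln(109/36)/22 h⁻¹ (peak 109 at 2 h, 36 at 24 h); 4 °C Optisol
k = ln(99/89)/166 h⁻¹ (99 at peak, 89 at 7 days). The dose slope is set so
the 2.67-µM working dose gives intensity 100 at peak, tying kinetics to the
default cytoplasm mean. The exponential decay form is an assumption — only
endpoint pairs are published — and `fit_decay` fits it anchored at the 2-h
peak by log-linear least squares.

## Patch photometry and the ROC cutoff

Patches are 25×25-pixel arrays; mean and SD are over all 625 pixels in
native grey levels. SNR = mean/SD (undefined for constant patches);
contrast = mean of viable patch means / mean of non-viable patch means,
unpaired, with the graft periphery as the standard non-viable reference and
a seeded 2000-resample bootstrap for the CI. Automatic patch placement is
rejection sampling of non-overlapping patches with a configurable minimum
in-region area fraction: 1.0 (fully inside) for contrast/SNR work, matching
arrays hand-placed in clean tissue; 0.9 for the classification benchmark, so
boundary-adjacent heterogeneity enters. The ROC sweeps integer thresholds
0–255 with "viable" as the positive class and strict `mean > t`
classification (so the default cutoff 40 excludes a mean of exactly 40);
AUC is trapezoidal over the swept curve with closed endpoints, and the
Youden-optimal threshold (ties to the lower threshold) is available as an
alternative to the fixed cutoff.

## Viability mapping

`detect_graft_mask` smooths, thresholds at the histogram valley (Otsu),
keeps the largest component and fits a least-squares (Kåsa) circle to its
boundary. This is reliable when the graft periphery is bright (undamaged or
streak-damaged grafts); with a wide non-viable rim the fitted disc tracks
the viable core, so synthetic workflows pass the generator's known geometry
instead — a documented limitation for rim-damaged real images.
`segment_viable` thresholds inside the mask and removes viable objects
below ~5 cell areas and holes below ~1 cell area (noise speckle at SNR 14
is sub-cell scale; both sizes configurable, 0 disables). Fractions are
computed over mask pixels and viable + damage fractions sum to 1 exactly.
Against truth rasterization the default calibrated render segments with
Dice ≥ 0.95. The raw thresholded fraction is monotone non-increasing in the
threshold; morphological cleanup can in principle perturb strict
monotonicity, so the property is guaranteed (and tested) with cleanup off.
Damage attribution rasterizes each footprint by pixel-center containment
and reports per-primitive recall plus leakage outside all footprints;
overlap areas are credited to every overlapping primitive and flagged.

## Morphometrics

`detect_nuclei` re-implements ImageJ-ITCN-style nucleus counting, whose
original parameters are unpublished: band-pass the image (Gaussian at
0.15× the expected cell width minus a 2×-cell-width background Gaussian),
take 3×3 local maxima above a 5-grey-level prominence, collapse tied
plateaus to their centroid, and accept strongest-first under a Euclidean
minimum separation of 0.7× cell width. At the defaults this gives recall
≈1.0 on the nuclear-counterstain channel and ≈0.925 on the calcein channel
(the undetectable-nucleus fraction), with precision ≈1. The band-pass
produces edge lobes at sharp viable/non-viable boundaries, so counting
regions should stay clear of damage edges (the benchmarks count a central
square). Density = count/area in cells/mm².

Hexagonality uses Voronoi adjacency: two cells are neighbors when their
regions share an edge longer than 10⁻³ of the median nearest-neighbor
spacing (shorter contacts are the broken four-corner degeneracy of
near-square arrangements, not true adjacencies — a jittered square lattice
correctly reads 4 neighbors per cell and 0% hexagonality). Cells whose
region is unbounded or touches the field bounds are excluded from the
percentage but still count as neighbors, standard border handling in
endothelial morphometry. The statistic is exactly invariant to translation,
uniform scaling and axis-preserving rotations; arbitrary rotations change
the axis-aligned exclusion box and can shift the interior set slightly.
Cell-area CoV is population SD over mean. Dead fraction de-duplicates
live/dead detections within a matching radius, resolving conflicts to dead.
Report-grade morphometry requires ≥1000 analyzed cells. Point matching for
recall/precision is greedy nearest-pair within one cell radius, verified
against an optimal-assignment oracle in the tests.

## Agreement

Bland-Altman differences are reference − test with the nuclear-counterstain
counts as reference, so a positive bias means the calcein method
under-counts; differences are absolute (cells/mm²). Limits of agreement use
the 1.96 normal quantile (t-quantile variant by flag); the bias CI is
t-based. Pearson r comes with the two-sided t-transform p-value.

## Benchmark problem sizes

The benchmarks keep every photometric and cellular default but run grafts at
3 mm diameter (≈17,700 cells at 2500 cells/mm²) and high-magnification
fields as 0.8-mm discs at 0.8 µm/px with a central 480-µm counting square.
Contrast, SNR, the ROC operating point, density bias and area fractions are
intensive quantities independent of graft diameter, and the 3-mm discs keep
a 10-graft photometry run plus a 20-replicate classification benchmark and a
20-field agreement study to a few minutes in total. The full 8-mm clinical
geometry remains the generator default and runs unchanged, just slower.

## What the synthetic benchmark does and does not show

The generator reproduces the assay's photometric structure (class means,
texture, noise, the three tissue classes, damage geometry) but idealizes
real imaging: illumination is uniform, frames are single (no averaging or
registration artifacts), optics are distortion-free (the source system shows
pincushion distortion, one plausible contributor to density under-counting
that is deliberately not modelled), grafts are flat discs rather than
scrolls, and the dead/bare class means are exactly piecewise-constant.
Passing benchmarks therefore demonstrates that the estimators are correct
and unbiased under the stated model — not that the specific operating point
(cutoff 40, sensitivity/specificity near 1) transfers to any given clinical
imaging system without recalibration. The calibrated synthetic images are
also cleanly separated by construction, so classification metrics at the
cutoff sit at or near 100%, comfortably above the published operating point;
the bit depth of the source exports is likewise an assumption (grey "units"
are treated as 8-bit levels).

## Numerical and degenerate-input conventions

Pixel coordinates are 0-based, row-major, origin top-left; physical
coordinates are µm from the graft center, with pixel centers at half-integer
offsets. Constant patches have undefined SNR (None). Constant decay series
fit rate 0 with R² 1. ROC requires both classes; contrast requires a
non-zero non-viable mean; collinear centroid sets, zero counting areas,
non-positive cell areas and empty channel pairs raise errors. Streak-width
bisection runs 40 iterations or until within tolerance. All seeds are
explicit; nothing touches global RNG state.
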