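# endoquant

Quantitative viability assessment of corneal endothelial (DMEK) grafts from
calcein-AM fluorescence images.

A DMEK graft is an 8-mm disc of Descemet membrane carrying the donor's
endothelial monolayer; the health of that monolayer decides the transplant's
fate. Staining the graft with calcein AM makes metabolically active cells
fluoresce brightly while attached dead cells and bare membrane stay near
black, so a single in-situ fluorescence image can be turned into numbers: a
viable-area fraction, a cell density, and mosaic-regularity indices.
`endoquant` implements that image-analysis chain and, because no public image
sets exist for this assay, pairs it with a fully ground-truthed synthetic
endothelial-mosaic generator so every estimator can be validated against
known truth.

## What it computes

**Patch photometry.** Mean fluorescence over 25×25-pixel arrays;
SNR = patch mean / patch pixel SD; fluorescence contrast
C = mean viable-patch fluorescence / mean peripheral (non-viable) patch
fluorescence, with a bootstrap CI. An ROC sweep over grey-level cutoffs
(0–255) gives the operating point of the default threshold, 40 grey levels,
at which a patch is called viable when its mean exceeds the cutoff.

**Viability mapping.** Graft-disc detection (histogram threshold + circle
fit), threshold segmentation at the calibrated cutoff with sub-cell-scale
morphological cleanup, the viable-area fraction over the graft disc, and
attribution of detected damage to ground-truth damage footprints.

**Morphometrics.** ITCN-style nuclear-maxima counting (band-pass +
prominence-filtered local maxima with a minimum separation) for cell density;
Voronoi neighbor analysis for hexagonality (% of cells with exactly 6
neighbors); cell-area coefficient of variation; percent dead cells from
live/dead channel pairs.

**Agreement.** Bland-Altman analysis of paired density estimates
(bias = mean(reference − test), limits of agreement bias ± 1.96·SD, t-based
CI) plus Pearson correlation.

**Synthetic grafts.** Centroidal-Voronoi cell mosaics on a disc with damage
primitives (peripheral rim, incarceration wedge, ejection streaks, tears,
polygonal patches, a triangular orientation mark), a photometric render model
(region means on the 8-bit scale, Gaussian PSF, post-blur read noise), and
staining kinetics (linear in dose, peak at 2 h, storage-dependent exponential
decay). `calibrate_render` solves the free photometric parameters so rendered
grafts reproduce a target contrast and SNR exactly by construction.

## Worked example

```python
from endoquant import benchmarks
from endoquant.agreement import bland_altman

# contrast and SNR over 10 calibrated synthetic grafts (50+50 patches each)
result, snr, _ = benchmarks.contrast_snr_benchmark(seed=21, n_grafts=10)
print(f"contrast {result.contrast:.2f} "
      f"(95% CI {result.ci_low:.2f}-{result.ci_high:.2f}), SNR {snr:.2f}")
# -> contrast 15.31 (95% CI 15.10-15.52), SNR 14.28

# density agreement: nuclear counterstain vs calcein-based counting
ref, tst = benchmarks.paired_density_fields(seed=24, n_fields=20)
res = bland_altman(ref, tst)
print(f"bias {res.bias:.0f} cells/mm^2 (LoA {res.loa_low:.0f} to {res.loa_high:.0f})")
# -> bias 181 cells/mm^2 (LoA 117 to 244)
```

The contrast/SNR figures recover the calibration targets; the positive bias
says the calcein method under-counts cells, because a fraction of viable
cells shows no nuclear calcein contrast and contributes no countable maximum.

The numbered scripts under `analysis/` run the full study: damage-phenotype
gallery, photometry benchmark, viability mapping of a streak-damaged graft
(true viable fraction 0.73 → reported 73.8% at cutoff 40, Dice 0.994 against
truth), morphometry, density agreement, and staining-kinetics fits. Each
writes its tables under `results/`. A `endoquant` CLI exposes the same steps
(`simulate`, `segment`, `photometry`, `morpho`, `agree`, `pipeline`).

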