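"""Standard synthetic benchmarks: the study conditions shared by the analysis
drivers, the test suite and the acceptance script.

All benchmarks run on grafts that keep the generator's photometric and
cellular defaults (2500 cells/mm**2, calibrated render) but use a smaller
trephine diameter than a clinical 8-mm graft; contrast, SNR, ROC operating
points, density bias and viable-area fractions are intensive quantities that
do not depend on graft diameter, and the smaller discs keep simulation times
reasonable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from . import photometry
from .morphometrics import DetectionParams, detect_nuclei, estimate_density, points_in_rect
from .mosaic_synth import (
    VIABLE,
    DamageSpec,
    GroundTruthMosaic,
    MosaicSpec,
    RenderSpec,
    apply_damage,
    benchmark_rim_damage,
    calibrate_render,
    calibrate_streak_width,
    generate_mosaic,
    rasterize_states,
    render,
)
from .viability_map import ViabilityReport, segment_viable

__all__ = [
    "DEFAULT_TARGET_CONTRAST",
    "DEFAULT_TARGET_SNR",
    "BENCHMARK_GRAFT",
    "calibrated_render_spec",
    "graft_patch_samples",
    "contrast_snr_benchmark",
    "roc_patch_benchmark",
    "streak_graft_benchmark",
    "paired_density_fields",
    "FIELD_SPEC",
]

# Photometric calibration targets: printed contrast and SNR of calcein
# viability imaging on real DMEK grafts.
DEFAULT_TARGET_CONTRAST = 15.41
DEFAULT_TARGET_SNR = 14.27

RIM_WIDTH_UM = 400.0
PATCH_SIDE = 25

# Global-view benchmark graft (trephine scaled down from the clinical 8 mm).
BENCHMARK_GRAFT = MosaicSpec(
    graft_diameter_mm=3.0, target_density=2500.0, regularity=10, pixel_size_um=5.0
)

# High-magnification field for density/morphometry work.
FIELD_SPEC = MosaicSpec(
    graft_diameter_mm=0.8, target_density=2500.0, regularity=10, pixel_size_um=0.8
)
FIELD_COUNT_SIDE_UM = 480.0  # central counting square


@lru_cache(maxsize=1)
def calibrated_render_spec() -> RenderSpec:
    """The default render spec calibrated to the module-default targets."""
    return calibrate_render(DEFAULT_TARGET_CONTRAST, DEFAULT_TARGET_SNR)


def _region_masks(gt: GroundTruthMosaic) -> tuple[np.ndarray, np.ndarray]:
    """(viable, non-viable) pixel masks from the ground-truth state raster."""
    _, inside, state_map = rasterize_states(gt)
    viable = state_map == VIABLE
    nonviable = inside & ~viable
    return viable, nonviable


def graft_patch_samples(
    seed: int,
    n_per_group: int = 50,
    damage: DamageSpec | None = None,
    spec: MosaicSpec | None = None,
    render_spec: RenderSpec | None = None,
    min_inside: float = 1.0,
) -> tuple[list[photometry.PatchSample], list[photometry.PatchSample]]:
    """One damaged graft with labeled viable / peripheral non-viable patches.

    Renders a graft carrying the standard non-viable periphery (bare DM edged
    by attached dead cells) plus any extra damage, then draws
    ``n_per_group`` 25x25 patches from the viable interior and the
    non-viable regions.  ``min_inside`` is the minimum patch-area fraction
    inside the region: 1.0 emulates arrays placed in clean tissue (the
    contrast/SNR measurement); 0.9 lets boundary-adjacent heterogeneity into
    the classification benchmark.
    """
    spec = spec or BENCHMARK_GRAFT
    render_spec = render_spec or calibrated_render_spec()
    gt = generate_mosaic(replace(spec, rng_seed=seed))
    gt = apply_damage(gt, benchmark_rim_damage(RIM_WIDTH_UM))
    if damage is not None:
        gt = apply_damage(gt, damage)
    img = render(gt, render_spec, seed=seed + 1)["calcein"]
    viable_mask, nonviable_mask = _region_masks(gt)
    viable = photometry.sample_patches_in_mask(
        img, viable_mask, n_per_group, side=PATCH_SIDE, label="viable", seed=seed + 2,
        min_inside=min_inside,
    )
    nonviable = photometry.sample_patches_in_mask(
        img, nonviable_mask, n_per_group, side=PATCH_SIDE, label="non_viable",
        seed=seed + 3, min_inside=min_inside,
    )
    return viable, nonviable


def contrast_snr_benchmark(
    seed: int, n_grafts: int = 10, n_per_group: int = 50
) -> tuple[photometry.ContrastResult, float, list[photometry.PatchSample]]:
    """Pooled contrast and mean viable-patch SNR over seeded calibrated grafts.

    Returns (contrast result over all pooled patches, mean viable SNR,
    the pooled viable patches).
    """
    all_viable: list[photometry.PatchSample] = []
    all_nonviable: list[photometry.PatchSample] = []
    rng = np.random.default_rng(seed)
    for _ in range(n_grafts):
        sub = int(rng.integers(2**31 - 1))
        v, nv = graft_patch_samples(sub, n_per_group=n_per_group)
        all_viable.extend(v)
        all_nonviable.extend(nv)
    result = photometry.contrast(all_viable, all_nonviable, seed=seed)
    snrs = [p.snr for p in all_viable if p.snr is not None]
    return result, float(np.mean(snrs)), all_viable


def roc_patch_benchmark(
    seed: int, n_replicates: int = 20, cutoff: float = 40.0
) -> tuple[float, float, float]:
    """Mean (sensitivity, specificity, AUC) at a fixed cutoff over seeded replicates.

    Each replicate is one damaged graft contributing 50 viable and 50
    non-viable labeled patches, classified viable when the patch mean is
    strictly above the cutoff.
    """
    rng = np.random.default_rng(seed)
    sens, spec, auc = [], [], []
    for _ in range(n_replicates):
        sub = int(rng.integers(2**31 - 1))
        v, nv = graft_patch_samples(sub, min_inside=0.9)
        res = photometry.roc(v + nv, cutoff=cutoff)
        sens.append(res.sensitivity_at_cutoff)
        spec.append(res.specificity_at_cutoff)
        auc.append(res.auc)
    return float(np.mean(sens)), float(np.mean(spec)), float(np.mean(auc))


@dataclass(frozen=True)
class StreakGraftResult:
    true_viable_fraction: float
    report: ViabilityReport
    gt: GroundTruthMosaic


def streak_graft_benchmark(
    seed: int,
    target_viable_fraction: float = 0.73,
    threshold: float = 40.0,
) -> StreakGraftResult:
    """Ejection-streak graft at a known true viable fraction, segmented at 40.

    Streak widths are auto-calibrated so the ground-truth viable-area
    fraction matches ``target_viable_fraction``; the graft is rendered with
    the calibrated defaults and segmented inside the known graft disc.
    """
    gt = generate_mosaic(replace(BENCHMARK_GRAFT, rng_seed=seed))
    streaks = calibrate_streak_width(gt, target_viable_fraction, count=5,
                                     orientation_deg=30.0)
    gt = apply_damage(gt, DamageSpec((streaks,)))
    img = render(gt, calibrated_render_spec(), seed=seed + 1)["calcein"]
    _, inside, _ = rasterize_states(gt)
    report = segment_viable(
        img, inside, threshold=threshold, pixel_size_um=gt.spec.pixel_size_um, truth=gt
    )
    return StreakGraftResult(
        true_viable_fraction=gt.true_viable_fraction, report=report, gt=gt
    )


def field_detection_params() -> DetectionParams:
    cell_width_px = 1000.0 / np.sqrt(FIELD_SPEC.target_density) / FIELD_SPEC.pixel_size_um
    return DetectionParams(cell_width_px=float(cell_width_px))


def paired_density_fields(
    seed: int, n_fields: int = 20, spec: MosaicSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Paired density estimates from high-magnification fields.

    For each field: render the calcein and nuclear-counterstain channels of
    the same mosaic, count nuclear maxima in each within a central
    480x480-um square, and convert to cells/mm**2.  Returns
    (nuclei-channel densities, calcein densities): the reference and test
    methods of the agreement analysis.
    """
    spec = spec or FIELD_SPEC
    params = field_detection_params()
    rspec = calibrated_render_spec()
    n_img = spec.resolved_image_size
    half_px = FIELD_COUNT_SIDE_UM / 2.0 / spec.pixel_size_um
    lo, hi = int(round(n_img / 2 - half_px)), int(round(n_img / 2 + half_px))
    area_mm2 = ((hi - lo) * spec.pixel_size_um / 1000.0) ** 2

    rng = np.random.default_rng(seed)
    ref, tst = [], []
    for _ in range(n_fields):
        sub = int(rng.integers(2**31 - 1))
        gt = generate_mosaic(replace(spec, rng_seed=sub))
        channels = render(gt, rspec, seed=sub + 1, channels=("calcein", "nuclei"))
        d = {}
        for ch, method in (("nuclei", "nuclei_channel"), ("calcein", "calcein_maxima")):
            pts = detect_nuclei(channels[ch], params)
            pts = points_in_rect(pts, (lo, hi), (lo, hi))
            d[ch] = estimate_density(pts, area_mm2, method=method).density
        ref.append(d["nuclei"])
        tst.append(d["calcein"])
    return np.asarray(ref), np.asarray(tst)
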