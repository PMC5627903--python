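import numpy as np
import pytest
from dataclasses import replace

from endoquant import benchmarks
from endoquant.mosaic_synth import MosaicSpec, generate_mosaic, render


@pytest.fixture(scope="session")
def calibrated_spec():
    """Render spec calibrated to the default contrast/SNR targets (cached)."""
    return benchmarks.calibrated_render_spec()


@pytest.fixture(scope="session")
def small_spec():
    return MosaicSpec(
        graft_diameter_mm=1.6, target_density=2500.0, regularity=5,
        pixel_size_um=5.0, rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_gt(small_spec):
    return generate_mosaic(small_spec)


@pytest.fixture(scope="session")
def small_image(small_gt, calibrated_spec):
    return render(small_gt, calibrated_spec, seed=12)["calcein"]


@pytest.fixture(scope="session")
def field():
    """One high-magnification field: ground truth plus calcein/nuclei channels."""
    gt = generate_mosaic(replace(benchmarks.FIELD_SPEC, rng_seed=42))
    channels = render(gt, benchmarks.calibrated_render_spec(), seed=43,
                      channels=("calcein", "nuclei"))
    return gt, channels


@pytest.fixture(scope="session")
def field_truth_px(field):
    gt, _ = field
    n = gt.spec.resolved_image_size
    return gt.nucleus_centers[:, ::-1] / gt.spec.pixel_size_um + n / 2.0
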