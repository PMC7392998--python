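import numpy as np
import pytest

from dualkin.phantom import (
    PhantomSpec,
    Region,
    build_phantom,
    dce_frame_schedule,
    default_phantom_spec,
    pet_frame_schedule,
)
from dualkin.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def pet_schedule():
    return pet_frame_schedule()


@pytest.fixture(scope="session")
def dce_schedule():
    return dce_frame_schedule()


@pytest.fixture(scope="session")
def noiseless_run():
    """Full pipeline on the default noiseless phantom (validation mode).

    Smoothing is disabled so per-voxel recovery can be compared against
    ground truth without resolution blurring; shared across test modules
    because the run is the expensive part of the suite.
    """
    config = PipelineConfig(
        phantom_spec=default_phantom_spec(seed=1),
        smoothing_fwhm_mm=0.0,
        pet_noise_scale=0.0,
        dce_noise_frac=0.0,
        n_boot=200,
        seed=1,
    )
    return run_pipeline(config)


def small_phantom_spec(seed: int = 0, jitter: float = 0.05) -> PhantomSpec:
    """A miniature two-region phantom (~60 tumor voxels) for fast tests."""
    rim = Region(
        name="rim", center_mm=(44.0, 32.0, 12.0), radii_mm=(6.0, 5.0, 4.0),
        pet=(0.15, 0.30, 0.05, 0.10), dce=(0.25, 0.35, 0.06), t10_s=1.4,
    )
    core = Region(
        name="core", center_mm=(44.0, 32.0, 12.0), radii_mm=(3.0, 2.5, 2.0),
        pet=(0.08, 0.25, 0.15, 0.03), dce=(0.06, 0.25, 0.015), t10_s=1.4,
    )
    return PhantomSpec(
        shape=(32, 32, 12), regions=[rim, core],
        aorta_center_mm=(14.0, 14.0), aorta_radius_mm=10.0,
        aorta_voi_radius_mm=5.0, aorta_voi_z_mm=(6.0, 18.0),
        jitter_frac=jitter, seed=seed,
    )


@pytest.fixture()
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_ground_truth():
    return build_phantom(small_phantom_spec(seed=3))
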