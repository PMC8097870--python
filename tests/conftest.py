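import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from optoflux.calibration import O2Calibration, PhCalibration
from optoflux.simulate import AcquisitionSpec, CellType, Chamber, Patch, SceneSpec


@pytest.fixture
def o2_cal() -> O2Calibration:
    return O2Calibration(R0=1.6, Ksv=0.03, batch_id="batch-A")


@pytest.fixture
def ph_cal() -> PhCalibration:
    return PhCalibration(R_acid=0.5, R_base=2.0, pKa=7.0, s=1.0, batch_id="batch-A")


def uniform_scene(grid=(32, 32), density=66_000.0, k_o2=1e-6, k_ph=4e-9,
                  d_eff=0.0, pixel_size_mm=0.1) -> SceneSpec:
    """Whole-grid lawn of one cell type; the parameter-recovery workhorse."""
    h, w = grid
    return SceneSpec(
        grid_shape=grid, pixel_size_mm=pixel_size_mm,
        patches=[Patch(shape="rect", params=[0, 0, h, w], cell_type="lawn")],
        cell_types={"lawn": CellType(density=density, k_o2=k_o2, k_ph=k_ph)},
        chamber=Chamber(height_mm=0.1, reference_height_mm=0.1, D_eff_mm2_per_s=d_eff),
    )


def patch_scene(grid=(64, 64), patch=(16, 16, 48, 48), density=66_000.0,
                k_o2=1e-6, d_eff=1e-3, pixel_size_mm=0.1) -> SceneSpec:
    """One square tumour patch on an empty background."""
    return SceneSpec(
        grid_shape=grid, pixel_size_mm=pixel_size_mm,
        patches=[Patch(shape="rect", params=list(patch), cell_type="tumour")],
        cell_types={"tumour": CellType(density=density, k_o2=k_o2)},
        chamber=Chamber(height_mm=0.1, reference_height_mm=0.1, D_eff_mm2_per_s=d_eff),
    )


def quiet_acquisition(interval_s=20.0, duration_s=400.0, seed=0) -> AcquisitionSpec:
    return AcquisitionSpec(interval_s=interval_s, duration_s=duration_s,
                           read_noise_sd=0.0, shot_noise=False, seed=seed)


def noisy_acquisition(interval_s=20.0, duration_s=400.0, seed=0) -> AcquisitionSpec:
    """Default camera-noise conditions: shot noise plus 5-unit read noise."""
    return AcquisitionSpec(interval_s=interval_s, duration_s=duration_s,
                           read_noise_sd=5.0, shot_noise=True, seed=seed)
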