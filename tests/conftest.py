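import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import translocq as tq

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def optics():
    """Far-red marker on a 1.45 NA objective at 160 nm/px (Airy ~1.68 px)."""
    return tq.OpticalConfig(wavelength=640.0, numerical_aperture=1.45, pixel_size=160.0)


@pytest.fixture(scope="session")
def noiseless_scene():
    return tq.SceneSpec(poisson_scale=0.0, read_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_render(noiseless_scene):
    return tq.render_confocal_timelapse(noiseless_scene)


@pytest.fixture(scope="session")
def noisy_render():
    return tq.render_confocal_timelapse(tq.SceneSpec(seed=11))


def rois_from_truth(truth) -> tq.RoiSet:
    return tq.RoiSet(
        cell=truth.cell_mask,
        cytosol=truth.cytosol_mask,
        background=truth.background_mask,
        nucleus=truth.nucleus_mask,
    )


def truth_masks(stack, truth) -> np.ndarray:
    return np.broadcast_to(
        truth.compartment_mask, (stack.n_frames, *stack.shape_yx)
    )
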