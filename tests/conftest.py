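import warnings

import numpy as np
import pytest

from ramanmsi import phantom as ph
from ramanmsi import readout as ro
from ramanmsi.acquisition import AcquisitionConfig

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def library():
    return ph.build_spectral_library()


@pytest.fixture(scope="session")
def true_calib():
    return ro.default_true_calibration()


@pytest.fixture()
def cfg():
    """Default (noisy) acquisition configuration."""
    return AcquisitionConfig()


@pytest.fixture()
def quiet_cfg():
    """Noise-free acquisition: expected counts only, no jitter or cosmics."""
    return AcquisitionConfig(noise=False, dispersion_jitter_cm1=0.0,
                             cosmic_ray_rate=0.0)


@pytest.fixture(scope="session")
def small_phantom():
    layout = ph.default_layout((128, 128))
    return ph.render_phantom(layout, pixel_size=4.0, seed=7)


def fat_batch_beams(n=6):
    """Six fat-class beams spread over the FOV with valid separations."""
    from ramanmsi.acquisition import BeamSpec

    pos = [(0.0, 0.0), (-60.0, -30.0), (40.0, -20.0), (-30.0, -10.0),
           (70.0, 10.0), (20.0, 20.0)][:n]
    return [BeamSpec(i, x, y, "fat", zero_order=(i == 0))
            for i, (x, y) in enumerate(pos)]
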