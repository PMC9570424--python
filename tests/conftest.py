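import numpy as np
import pytest

from flimcyto import (AcquisitionConfig, DEFAULT_GROUP_PROFILES,
                      render_cell_layout, simulate_tcspc_image)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale acquisition: 64 px field, 32 time bins, 20 ns period."""
    return AcquisitionConfig(image_size_px=64, n_time_bins=32)


@pytest.fixture(scope="session")
def default_config():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def normal_profile():
    return DEFAULT_GROUP_PROFILES["normal"]


@pytest.fixture(scope="session")
def cc_profile():
    return DEFAULT_GROUP_PROFILES["CC"]


@pytest.fixture(scope="session")
def small_image(small_config, normal_profile):
    """One simulated normal-group acquisition with its ground truth."""
    phantoms, maps = render_cell_layout(3, normal_profile, small_config,
                                        seed=2024)
    image = simulate_tcspc_image(maps, small_config, seed=2025)
    return image, phantoms, maps


def biexp_expected(a2, t2, amplitude, config, background=0.0):
    """Dense expected histogram of the biexponential model (test oracle)."""
    tau = config.bin_centers_ps
    e1 = np.exp(-tau / config.t1_ps)
    e1 = e1 / e1.sum()
    e2 = np.exp(-tau / t2)
    e2 = e2 / e2.sum()
    return amplitude * ((1 - a2) * e1 + a2 * e2) + background
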