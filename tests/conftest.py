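import numpy as np
import pytest

from ihrf import VolumeSpec, generate_surfaces


@pytest.fixture(scope="session")
def noise_free_spec():
    return VolumeSpec(speckle_shape=0.0)


@pytest.fixture(scope="session")
def flat_surfaces(noise_free_spec):
    """Default phantom surfaces: constant retinal thickness."""
    return generate_surfaces(noise_free_spec)


@pytest.fixture(scope="session")
def small_spec():
    """A small phantom for fast per-test rendering."""
    return VolumeSpec(n_ascans_x=64, n_bscans_y=16, n_depth_z=128, speckle_shape=0.0)


@pytest.fixture(scope="session")
def small_surfaces(small_spec):
    return generate_surfaces(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
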