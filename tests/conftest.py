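import numpy as np
import pytest

from prcpet import (AcquisitionConfig, ImageVolume, make_rod5_phantom,
                    make_sphere1_phantom)


@pytest.fixture(scope="session")
def small_rod5():
    """Coarse five-rod phantom small enough for brute-force oracles."""
    return make_rod5_phantom(10.0, voxel_size_mm=1.6, shape=(48, 48, 40))


@pytest.fixture(scope="session")
def small_sphere1():
    return make_sphere1_phantom(voxel_size_mm=1.6, shape=(48, 48, 40))


@pytest.fixture(scope="session")
def small_acq():
    """Acquisition tuned down for unit tests (coarse grid, modest counts)."""
    return AcquisitionConfig(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_image(data, voxel=1.0, provenance="gamma", cid="fixture"):
    return ImageVolume(data=np.asarray(data, dtype=np.float32),
                       voxel_size_mm=voxel, provenance=provenance,
                       source_config_id=cid)
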