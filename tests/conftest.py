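import numpy as np
import pytest

from aamhop import fixtures as fx


@pytest.fixture(scope="session")
def geometry():
    return fx.fixture_geometry()


@pytest.fixture(scope="session")
def mask():
    return fx.fixture_mask()


@pytest.fixture(scope="session")
def small_search():
    """24 deduplicated rotations (90° step), ±2 Å translations."""
    return fx.fixture_search(angle_step=90.0)


@pytest.fixture(scope="session")
def ref_descriptor():
    return fx.random_descriptor(11)


@pytest.fixture(scope="session")
def lib_descriptor():
    return fx.random_descriptor(22)


@pytest.fixture(scope="session")
def gaussian_grid(geometry):
    """A smooth spherically symmetric field, well inside the extent."""
    pts = geometry.voxel_centers()
    vals = np.exp(-np.sum(pts**2, axis=-1) / (2 * 2.0**2))
    return geometry.copy_with(vals)
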