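import numpy as np
import pytest

from octquant.phantom import (FoveaSpec, PhantomSpec, SpeckleModel,
                              generate_volume)

# Small grids keep the suite fast; the full instrument geometry is exercised
# only where a test depends on it.
SMALL_GRID = (48, 24, 176)
SMALL_VOXEL = (125.0, 250.0, 2.3)


def small_spec(seed=0, speckle_shape=None, pit=True, **kw):
    fovea = kw.pop("fovea", FoveaSpec() if pit else FoveaSpec(pit_depth_um=0.0))
    kw.setdefault("ilm_offset_um", 40.0)
    return PhantomSpec(grid_shape=SMALL_GRID, voxel_size=SMALL_VOXEL,
                       seed=seed, speckle=SpeckleModel(shape=speckle_shape),
                       fovea=fovea, **kw)


def planar_spec(seed=0, speckle_shape=None, **kw):
    return small_spec(seed=seed, speckle_shape=speckle_shape, pit=False,
                      curvature_um=0.0, thickness_ripple_frac=0.0, **kw)


@pytest.fixture(scope="session")
def planar_volume():
    """Noise-free planar phantom shared across read-only tests."""
    return generate_volume(planar_spec(seed=10))


@pytest.fixture(scope="session")
def pit_volume():
    """Noise-free phantom with foveal pit and bowing."""
    return generate_volume(small_spec(seed=11))


@pytest.fixture(scope="session")
def speckled_volume():
    return generate_volume(small_spec(seed=12, speckle_shape=12.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
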