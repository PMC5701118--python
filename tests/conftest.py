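import numpy as np
import pytest

from parapatry.grids import SuitabilityGrid
from parapatry.simulate import MorphoSimConfig, gen_landmark_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture
def random_grid_pair(rng):
    """Two random suitability grids on one georeference (for oracles)."""
    shape = (23, 31)
    def make():
        values = rng.uniform(0, 1, size=shape)
        values[rng.uniform(size=shape) < 0.05] = np.nan  # scattered nodata
        return SuitabilityGrid(values, origin_lon=-53.0, origin_lat=-34.0,
                               cell_size=0.1)
    return make(), make()


@pytest.fixture(scope="session")
def default_sample():
    """One simulated 85-specimen landmark sample (study-design defaults)."""
    return gen_landmark_sample(MorphoSimConfig(seed=11))


@pytest.fixture(scope="session")
def null_sample():
    """A no-displacement sample (delta = 0) at the default design."""
    return gen_landmark_sample(MorphoSimConfig(seed=12, delta=0.0))


def random_rigid_transform(rng, scale_range=(0.2, 5.0)):
    """Random rotation matrix, translation and positive scale."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    translation = rng.uniform(-20, 20, size=2)
    scale = rng.uniform(*scale_range)
    return rot, translation, scale
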