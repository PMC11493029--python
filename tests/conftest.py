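import numpy as np
import pytest

from mcrisk import BasinScenario, Raster, packaged_wq_table
from mcrisk.synthetic_basin import generate_basin


@pytest.fixture(scope="session")
def wq_table():
    return packaged_wq_table()


@pytest.fixture(scope="session")
def default_basin():
    """One realization of the default 128×128 scenario (seed 1)."""
    return generate_basin(BasinScenario(seed=1))


@pytest.fixture
def small_raster():
    rng = np.random.default_rng(7)
    return Raster(values=rng.uniform(0, 10, size=(9, 11)), cell_size=30.0,
                  origin=(1000.0, 5000.0), semantic="dem")


def random_resistance(seed: int, shape=(15, 15), nodata_frac: float = 0.0):
    """Seeded resistance raster with values in [1, 9]."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1, 9, size=shape)
    r = Raster(values=vals, cell_size=10.0, semantic="resistance")
    if nodata_frac > 0:
        holes = rng.random(shape) < nodata_frac
        holes[0, 0] = False
        v = r.values.copy()
        v[holes] = r.nodata
        r = Raster(values=v, cell_size=10.0, semantic="resistance")
    return r
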