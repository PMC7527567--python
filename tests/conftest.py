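import numpy as np
import pytest

from ecoland.grids import CategoricalRaster, default_scheme
from ecoland.synth import SyntheticConfig, generate_scenario


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_raster(values, cell_size=30.0, origin=(0.0, 0.0), year=None, mask=None):
    return CategoricalRaster(np.asarray(values, dtype=np.int64), mask,
                             cell_size, origin, year=year)


@pytest.fixture(scope="session")
def small_scenario(scheme):
    """One 64x64 two-date scenario shared by read-only tests."""
    cfg = SyntheticConfig(seed=42, shape=(64, 64), dates=(1991, 2000))
    return generate_scenario(cfg, scheme)


@pytest.fixture(scope="session")
def full_scenario(scheme):
    """A 96x96 four-date scenario for pipeline-level tests."""
    cfg = SyntheticConfig(seed=7, shape=(96, 96))
    return generate_scenario(cfg, scheme)
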