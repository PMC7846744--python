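import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from amocrange import (
    GridSpec,
    WorldSpec,
    generate_climate_world,
    generate_virtual_species,
    make_realm_mask,
)


@pytest.fixture(scope="session")
def small_world():
    """A 20x40 two-realm world shared by read-only tests."""
    spec = WorldSpec(
        grid_shape=(20, 40), n_realms=2, seed=42, horizons=(2030, 2070)
    )
    return generate_climate_world(spec)


@pytest.fixture(scope="session")
def small_species(small_world):
    return generate_virtual_species(small_world, 6, seed=11)


@pytest.fixture
def grid_3x6():
    return GridSpec(3, 6, 1.0)


@pytest.fixture
def mask_3x6(grid_3x6):
    """Two realms: columns 0-2 and 3-5."""
    return make_realm_mask(grid_3x6, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
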