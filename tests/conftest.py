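import numpy as np
import pytest

from neevar import GridGeometry, SimConfig, generate_fieldset


@pytest.fixture(scope="session")
def toy_config():
    """A small, fast study: 15-deg grid, 16 years, defaults otherwise."""
    return SimConfig(seed=7, n_years=16, lat_step=15.0, lon_step=15.0)


@pytest.fixture(scope="session")
def toy_fieldset(toy_config):
    fieldset, truth = generate_fieldset(toy_config)
    return fieldset, truth


@pytest.fixture
def tiny_geometry():
    """4 x 6 grid, all land."""
    return GridGeometry.regular(45.0, 60.0, np.ones((4, 6), dtype=bool))
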