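import numpy as np
import pytest

from pmadjoint import (GridSpec, MetFields, SpeciesSet, WorldConfig,
                       make_scenario, make_world)


@pytest.fixture(scope="session")
def species():
    return SpeciesSet()


@pytest.fixture
def small_grid():
    return GridSpec(nx=6, ny=5, dx_km=100.0, dt_s=3600.0, n_hours=12,
                    boundary="periodic")


@pytest.fixture
def calm_met(small_grid, species):
    nh = small_grid.n_hours
    shape = (nh, small_grid.ny, small_grid.nx)
    return MetFields(np.zeros(shape), np.zeros(shape),
                     np.ones((nh, len(species.conversions))))


@pytest.fixture(scope="session")
def box_world():
    return make_world(make_scenario("box"))


@pytest.fixture(scope="session")
def plume_world():
    return make_world(make_scenario("plume"))


@pytest.fixture(scope="session")
def default_world():
    """The seeded study world: 30x30 cells, 240 hours, linear chemistry."""
    return make_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def titration_world():
    return make_world(make_scenario("titration_demo", seed=3))
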