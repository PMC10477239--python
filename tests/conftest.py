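import numpy as np
import pytest

from invasim.grids import Grid, LandUseMap, PresenceMap
from invasim.hsi import project_scores
from invasim.invasion import initial_density
from invasim.synthetic import ScenarioSpec, make_landscape, make_scenario, sample_presence


@pytest.fixture(scope="session")
def small_scenario():
    """Seed-42 20x20 infestation fixture shared by control-stage tests."""
    spec = ScenarioSpec(shape=(20, 20), n_classes=4, blob_scale=2.0,
                        presence_rate=0.2, seed=42)
    lu, presence = make_scenario(spec)
    hsi = project_scores(lu, {c: s / sum(spec.true_scores.values())
                              for c, s in spec.true_scores.items()})
    state0 = initial_density(presence, hsi)
    return dict(spec=spec, lu=lu, presence=presence, hsi=hsi, state0=state0)


@pytest.fixture(scope="session")
def medium_scenario():
    """100x100 scenario for estimation/validation tests."""
    spec = ScenarioSpec(shape=(100, 100), n_classes=8, blob_scale=4.0,
                        presence_rate=0.08, seed=7)
    lu, presence = make_scenario(spec)
    return dict(spec=spec, lu=lu, presence=presence)


@pytest.fixture
def checker_lu():
    """4x4 land-use map, left half class 1, right half class 2."""
    values = np.array([[1, 1, 2, 2]] * 4)
    return LandUseMap(values=values, cellsize=20.0, class_table={1: "A", 2: "B"})


def uniform_grid(value, shape=(5, 5), cellsize=20.0):
    return Grid(values=np.full(shape, float(value)), cellsize=cellsize)
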