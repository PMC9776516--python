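import numpy as np
import pytest

from ionatmos import GridSpec, IonTrajectory, StructureModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_structure(rng):
    """20 random atoms with assorted charges and radii in a 10 Å cube."""
    n = 20
    return StructureModel(
        positions=rng.uniform(-5, 5, size=(n, 3)),
        charges=rng.uniform(-1, 1, size=n),
        radii=rng.uniform(1.0, 2.5, size=n),
    )


@pytest.fixture
def small_gridspec():
    """9³ nodes, 1 Å mesh, centred on the origin."""
    return GridSpec.cube((0.0, 0.0, 0.0), 8.0, 1.0)


@pytest.fixture
def uniform_trajectory(rng):
    """10 frames of uniform non-interacting particles in a 20 Å box."""
    species = np.array(["CAT"] * 4 + ["ANI"] * 4 + ["WAT"] * 30, dtype=object)
    frames = rng.uniform(0, 20, size=(10, len(species), 3))
    return IonTrajectory(frames, species, (20.0, 20.0, 20.0))
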