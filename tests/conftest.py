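import matplotlib
matplotlib.use("Agg")

import numpy as np
import pytest

from interleaf.cube import BandGrid, default_grid
from interleaf import simkit


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """31-band grid used by the heavier raster experiments."""
    return BandGrid(np.arange(400.0, 1000.1, 20.0))


@pytest.fixture(scope="session")
def table2():
    return simkit.table2_specs()


@pytest.fixture(scope="session")
def leafspot_scene(grid, table2):
    """One diseased scene with masks, deterministic."""
    return simkit.simulate_cube(table2[1], grid, 64, 64, seed=7)


@pytest.fixture(scope="session")
def healthy_scene(grid, table2):
    return simkit.simulate_cube(table2[0], grid, 64, 64, seed=7)
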