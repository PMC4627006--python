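import numpy as np
import pytest

from greennet.grid import GridRaster
from greennet.synthetic import LandscapeSpec, generate_landscape


@pytest.fixture
def single_patch_raster():
    """10x10 background grid with one 3x3 patch of class 1 (10 m cells)."""
    values = np.zeros((10, 10), dtype=np.int64)
    values[3:6, 3:6] = 1
    return GridRaster(values=values, cell_size=10.0)


@pytest.fixture
def two_class_raster():
    """6x6 grid: left half class 1, right half class 2 (equal areas)."""
    values = np.ones((6, 6), dtype=np.int64)
    values[:, 3:] = 2
    return GridRaster(values=values, cell_size=10.0)


def random_raster(seed, rows=20, cols=20, proportions=None, clumping=4):
    """Seeded random-cluster landscape used across oracle-equivalence tests."""
    proportions = proportions or {1: 0.25, 2: 0.15}
    return generate_landscape(
        LandscapeSpec(
            rows=rows, cols=cols, proportions=proportions, clumping=clumping,
            seed=seed,
        )
    )
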