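import numpy as np
import pytest

from walkaccess.core_grid import GeoGrid, METRES_PER_DEGREE

CELL_20M = 20.0 / METRES_PER_DEGREE


def make_grid(values, origin_lon=32.0, origin_lat=0.5, cell_size=CELL_20M):
    return GeoGrid(values=np.asarray(values, dtype=float),
                   origin_lon=origin_lon, origin_lat=origin_lat,
                   cell_size=cell_size)


@pytest.fixture
def grid_3x4():
    return make_grid(np.arange(12, dtype=float).reshape(3, 4))


def random_cost_array(rng, n_rows, n_cols, na_fraction=0.2):
    """Random seconds-per-cell surface with NaN patches, min cost 10 s."""
    costs = rng.uniform(10.0, 200.0, size=(n_rows, n_cols))
    mask = rng.random((n_rows, n_cols)) < na_fraction
    costs[mask] = np.nan
    return costs
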