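import numpy as np
import pandas as pd
import pytest

from amphex.climate import DailyTemperatureCube
from amphex.grid import GridSpec
from amphex.synthetic import SyntheticScenario


@pytest.fixture
def unit_grid() -> GridSpec:
    """4 x 2 grid of 0.5 degree cells with SW corner at (0, 0)."""
    return GridSpec.regular(0.0, 0.0, 4, 2, 0.5, 0.5)


@pytest.fixture
def tiny_scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=7, nlon=8, nlat=8, n_species=25)


def make_cube(values_1d, grid=None, start="1980-01-01", mask=None):
    """Single-cell daily cube from a 1-D series (helper for event tests)."""
    v = np.asarray(values_1d, dtype=float)
    grid = grid or GridSpec.regular(0.0, 0.0, 1, 1)
    dates = pd.date_range(start, periods=v.size, freq="D")
    cube_vals = v[:, None, None]
    m = None if mask is None else np.asarray(mask, bool)[:, None, None]
    return DailyTemperatureCube(grid, dates, cube_vals, mask=m)
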