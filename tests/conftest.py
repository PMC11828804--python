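import numpy as np
import pytest

import zonechip as zc
from zonechip import flow as fl
from zonechip import transport as tr


@pytest.fixture(scope="session")
def geometry():
    return zc.DeviceGeometry()


@pytest.fixture(scope="session")
def params(geometry):
    return zc.TransportParams.for_geometry(geometry)


@pytest.fixture(scope="session")
def grid(geometry):
    return zc.build_grid(geometry, nx=100, nz=50)


@pytest.fixture(scope="session")
def gas_gradient():
    """Zone-patterned gas boundary: air on zone 1, nitrogen on zone 3."""
    return tr.GasBC(high_percent=19.0, low_percent=0.0)


@pytest.fixture(scope="session")
def steady_no_cells(grid, params, gas_gradient):
    return tr.steady_oxygen(grid, params, gas_gradient)


@pytest.fixture(scope="session")
def steady_with_cells(grid, params, gas_gradient):
    cells = tr.CellField.uniform(grid, params)
    return tr.steady_oxygen(grid, params, gas_gradient, cells=cells)


@pytest.fixture(scope="session")
def velocity_at(geometry, grid):
    def make(q_ul_min):
        return fl.poiseuille_profile(fl.FlowSpec.from_ul_min(q_ul_min),
                                     geometry, grid)
    return make
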