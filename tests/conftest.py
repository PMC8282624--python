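import numpy as np
import pytest

from pftshift.synthetic_landscape import (
    EnvStack,
    GridSpec,
    NicheSpec,
    generate_landscape,
)


@pytest.fixture
def grid():
    return GridSpec(n_rows=20, n_cols=25, lat_min=4.0, lat_max=24.0,
                    lon_min=-100.0, lon_max=-68.0)


@pytest.fixture
def env(grid):
    return generate_landscape(grid, {"elevation_ramp": 2000.0}, seed=7)


@pytest.fixture
def flat_env(grid):
    """Spatially constant stack except for a west-east temperature ramp."""
    shape = grid.shape
    temp = np.tile(np.linspace(18, 30, grid.n_cols), (grid.n_rows, 1))
    return EnvStack(
        grid=grid,
        layers={
            "temperature": temp,
            "precipitation": np.full(shape, 1500.0),
            "elevation": np.zeros(shape),
        },
    )


@pytest.fixture
def warm_niche():
    return NicheSpec("warm_sp", {"temperature": 26.0}, {"temperature": 2.0}, 0.9)
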