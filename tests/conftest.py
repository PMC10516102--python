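import numpy as np
import pytest

from sdmpipe import ClimatePCA, ClimateStack, RasterGrid, SyntheticConfig, generate_climate


@pytest.fixture(scope="session")
def small_climate() -> ClimateStack:
    """A 40x40, 19-layer simulated present climate."""
    return generate_climate(SyntheticConfig(grid_rows=40, grid_cols=40, seed=11))


@pytest.fixture(scope="session")
def small_scores(small_climate) -> ClimateStack:
    """PCA score layers of the small climate."""
    return ClimatePCA().fit(small_climate).transform(small_climate)


@pytest.fixture
def unit_grid() -> RasterGrid:
    """8x8 all-ones grid with unit cells."""
    return RasterGrid(np.ones((8, 8)), x0=0.0, y0=8.0, cell_size=1.0)
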