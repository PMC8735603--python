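import numpy as np
import pandas as pd
import pytest

from esmsdm.raster import GridSpec, Raster, RasterStack
from esmsdm.synthetic import SpeciesSpec, SyntheticScenario, gen_study


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    return SyntheticScenario(grid_rows=50, grid_cols=50, n_plots=250, seed=11)


@pytest.fixture(scope="session")
def small_study(small_scenario):
    """A compact synthetic study: stack, plots, occurrences for 3 species."""
    species = [
        SpeciesSpec("sp_a", "moss", ("P1", "P2"), (0.0, 3.0, 0.0, 0.0), 20, seed=1),
        SpeciesSpec("sp_b", "liverwort", ("P2", "P3"), (0.0, 0.0, 3.0, 0.5), 12, seed=2),
        SpeciesSpec("sp_c", "sphagna", ("P4", "P5"), (-1.0, 2.5, -1.0, 0.0), 7, seed=3),
    ]
    return gen_study(small_scenario, species)


def make_raster(arr, cell_size=30.0) -> Raster:
    arr = np.asarray(arr, dtype=float)
    return Raster(arr, GridSpec(*arr.shape, cell_size=cell_size))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
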