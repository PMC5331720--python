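import numpy as np
import pandas as pd
import pytest

import phyloclim as pc
from phyloclim.trees import as_arrays


@pytest.fixture(scope="session")
def small_tree():
    """20-tip ultrametric Yule tree, fixed seed."""
    return pc.simulate_yule_tree(20, 0.2, seed=11)


@pytest.fixture(scope="session")
def small_arrays(small_tree):
    return as_arrays(small_tree)


@pytest.fixture(scope="session")
def climate_grid():
    return pc.simulate_climate_grid(seed=3)


@pytest.fixture(scope="session")
def sim_dataset(climate_grid):
    """Species, occurrence records and trait table from the generator."""
    tree = pc.simulate_yule_tree(40, 0.2, seed=21)
    ta = as_arrays(tree)
    cfg = pc.SimConfig(n_tips=40, records_per_species=30, seed=5)
    records, traits, info = pc.simulate_occurrences(
        ta.tip_labels, climate_grid, cfg, seed=5
    )
    return {"tree": tree, "records": records, "traits": traits,
            "info": info, "config": cfg}


def constant_climate_grid(t=20.0, p=100.0, nrows=4, ncols=4):
    from phyloclim.grid import ClimateGrid

    temp = np.full((12, nrows, ncols), t)
    prec = np.full((12, nrows, ncols), p)
    return ClimateGrid(lat_min=-2.0, lon_min=0.0, cellsize=1.0,
                       temp=temp, prec=prec)


@pytest.fixture
def flat_grid():
    return constant_climate_grid()


def make_records(rows):
    return pd.DataFrame(
        rows,
        columns=["species", "decimalLatitude", "decimalLongitude", "basisOfRecord"],
    )
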