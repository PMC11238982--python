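import numpy as np
import pandas as pd
import pytest

from basindiv import environment, occurrences, synthetic
from basindiv.grid import GridSpec


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(cell_size=1.0, lon_min=-80, lon_max=-72, lat_min=-40, lat_max=-32)


@pytest.fixture(scope="session")
def env_stack(small_grid):
    return synthetic.make_env_fields(small_grid, n_time_slices=4, spatial_scale=2.0, seed=1)


@pytest.fixture(scope="session")
def env_table(env_stack):
    return environment.env_table_from_stack(env_stack)


@pytest.fixture(scope="session")
def pool(env_table):
    return synthetic.make_species_pool(env_table, n_species=40, seed=1)


@pytest.fixture(scope="session")
def effort_field(env_table):
    return synthetic.uniform_effort(env_table, 8.0)


@pytest.fixture(scope="session")
def clean_records_fixture(env_table, pool, effort_field):
    """Records with no corruption, for exact reconstruction tests."""
    return synthetic.simulate_occurrences(env_table, pool, effort_field,
                                          dirty_fraction=0.0, seed=7)


@pytest.fixture(scope="session")
def dirty_records(env_table, pool, effort_field):
    return synthetic.simulate_occurrences(env_table, pool, effort_field,
                                          dirty_fraction=0.15, seed=7)


@pytest.fixture(scope="session")
def pam(clean_records_fixture, small_grid):
    rt = occurrences.record_table_from_frame(clean_records_fixture)
    cleaned, _ = occurrences.clean_records(rt)
    gridded = occurrences.assign_cells(cleaned, small_grid)
    return occurrences.build_pam(gridded)


@pytest.fixture(scope="session")
def gridded_records(clean_records_fixture, small_grid):
    rt = occurrences.record_table_from_frame(clean_records_fixture)
    cleaned, _ = occurrences.clean_records(rt)
    return occurrences.assign_cells(cleaned, small_grid)


def make_pam(counts, cells=None, species=None):
    """Hand-built PAM from a count matrix."""
    counts = np.asarray(counts)
    cells = cells or [f"{i}_0" for i in range(counts.shape[0])]
    species = species or [f"sp{j}" for j in range(counts.shape[1])]
    return occurrences.PAM(cells=cells, species=species, counts=counts)
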