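import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import methylpair as mp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> mp.SimConfig:
    return mp.SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_cfg):
    """One full simulated study shared across tests."""
    return mp.simulate_dataset(default_cfg)


@pytest.fixture(scope="session")
def called(dataset):
    """Filter -> tile -> test -> call on the shared dataset."""
    matrix = mp.filter_sites(dataset.counts)
    table = mp.tile_windows(matrix)
    tested = mp.test_windows(table)
    dmrset = mp.call_dmrs(tested, table)
    return matrix, table, tested, dmrset


def toy_matrix(sites, meth, total, groups=("adipogenic", "myogenic"),
               n_animals=3):
    """Hand-built CpGCountMatrix; sites is a list of (chrom, pos)."""
    samples = pd.DataFrame([
        {"name": f"{g}_{a}", "animal": a, "group": g}
        for g in groups for a in range(1, n_animals + 1)
    ])
    return mp.CpGCountMatrix(
        sites=pd.DataFrame(sites, columns=["chrom", "pos"]),
        samples=samples,
        meth=np.asarray(meth),
        total=np.asarray(total),
    )
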