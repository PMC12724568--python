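import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from best4pipe.data_io import ExpressionDataset
from best4pipe.synthetic_data import (
    SimSpec,
    simulate_multispecies,
    simulate_regional,
    simulate_trajectory_pair,
)

logging.getLogger("best4pipe").setLevel(logging.ERROR)


def make_dataset(counts, gene_ids=None, cell_ids=None, clusters=None, genotypes=None):
    """Hand-build a small ExpressionDataset from a dense count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    meta["cluster"] = clusters if clusters is not None else "all"
    meta["dataset_id"] = "test"
    meta["species"] = "testfish"
    meta["genotype"] = genotypes if genotypes is not None else "NA"
    meta["batch"] = "b0"
    meta["region"] = "NA"
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
        cell_meta=meta,
    )


@pytest.fixture(scope="session")
def sim_spec():
    return SimSpec(seed=0)


@pytest.fixture(scope="session")
def multispecies(sim_spec):
    return simulate_multispecies(sim_spec)


@pytest.fixture(scope="session")
def trajectory(sim_spec):
    return simulate_trajectory_pair(sim_spec)


@pytest.fixture(scope="session")
def regional(sim_spec):
    return simulate_regional(sim_spec)
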