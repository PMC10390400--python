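import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from orthoweave import SimulationConfig
from orthoweave.pipeline import run_synthetic_pipeline

warnings.filterwarnings("ignore", category=UserWarning, module="anndata")


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic study (seed 0); shared across tests."""
    return run_synthetic_pipeline(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced synthetic study for unit-level checks."""
    from orthoweave import CellTypeSpec
    from orthoweave.cluster import DEFAULT_MARKER_PANEL as P

    return SimulationConfig(
        n_ref_genes=300,
        cell_types=[
            CellTypeSpec("pit mucous cell", 60, P["pit mucous cell"]),
            CellTypeSpec("chief cell", 60, P["chief cell"]),
            CellTypeSpec("BGMC", 50, P["BGMC"]),
            CellTypeSpec("F3+ cell", 40, P["F3+ cell"]),
        ],
        seed=7,
    )


def make_counts(matrix, genes=None, barcodes=None, species="test"):
    """Small dense-matrix AnnData helper (rows = cells, columns = genes)."""
    m = np.asarray(matrix)
    genes = genes or [f"g{j}" for j in range(m.shape[1])]
    barcodes = barcodes or [f"c{i}" for i in range(m.shape[0])]
    obs = pd.DataFrame({"barcode": barcodes, "species": species}, index=barcodes)
    return AnnData(X=sp.csr_matrix(m), obs=obs, var=pd.DataFrame(index=genes))


@pytest.fixture
def counts_factory():
    return make_counts
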