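import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from xiescape import (
    AlleleCountDataset,
    SimulationConfig,
    build_truth,
    default_paper_like_config,
    simulate_dataset,
)


def make_dataset(xa, xi, cell_types=None, sample_ids=None, age_groups=None, chromosomes=None):
    """Hand-built dataset from dense arrays, with sensible default metadata."""
    xa = np.asarray(xa)
    n_cells, n_genes = xa.shape
    cells = pd.DataFrame(
        {
            "barcode": [f"bc{i}" for i in range(n_cells)],
            "cell_type": cell_types or ["CA1"] * n_cells,
            "sample_id": sample_ids or ["young_1"] * n_cells,
            "age_group": age_groups or ["young"] * n_cells,
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{j}" for j in range(n_genes)],
            "chromosome": chromosomes or (["1"] * (n_genes - 1) + ["X"] if n_genes > 1 else ["X"]),
        }
    )
    return AlleleCountDataset(
        sp.csr_matrix(np.asarray(xa, dtype=np.int64)),
        sp.csr_matrix(np.asarray(xi, dtype=np.int64)),
        cells,
        genes,
    )


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study conditions for fast end-to-end tests."""
    cfg = default_paper_like_config(seed=7)
    cfg.cells_per_type_per_sample = 30
    return cfg


@pytest.fixture(scope="session")
def small_sim(small_config):
    truth = build_truth(small_config)
    ds, truth = simulate_dataset(truth, small_config)
    return ds, truth


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        n_cell_types=2,
        cells_per_type_per_sample=10,
        n_samples_per_age=2,
        n_autosomal_genes=30,
        n_x_genes=10,
        mean_depth_per_cell=300.0,
        seed=5,
    )
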