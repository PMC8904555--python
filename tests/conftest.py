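import numpy as np
import pandas as pd
import pytest

from scgenolink.matrix import CellGeneMatrix
from scgenolink.simulate import SimConfig, simulate_dataset, write_fixture

#: one simulated dataset shared (read-only) across test modules
DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def fixture_dir(default_dataset, tmp_path_factory):
    directory = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(default_dataset, directory)
    return paths


def make_matrix(counts, samples=None) -> CellGeneMatrix:
    """Small literal matrix with generated ids (cells are rows)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cells = [f"c{i}" for i in range(n_cells)]
    genes = [f"g{j}" for j in range(n_genes)]
    samples = samples or ["s1"] * n_cells
    return CellGeneMatrix(counts, cells, genes, pd.Series(samples, index=cells))
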