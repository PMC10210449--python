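import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scsexbias.io_qc import CellMetadata, CountMatrix


def make_counts(dense, gene_ids=None, cell_ids=None) -> CountMatrix:
    dense = np.asarray(dense, dtype=np.int64)
    g, c = dense.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(c)]
    return CountMatrix(sp.csr_matrix(dense), gene_ids, cell_ids)


def make_meta(cell_ids, sample_ids, sexes, cell_types, replicates=None) -> CellMetadata:
    n = len(cell_ids)
    if replicates is None:
        replicates = ["1"] * n
    return CellMetadata(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "sample_id": sample_ids,
                "sex": sexes,
                "replicate": replicates,
                "cell_type": cell_types,
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_counts():
    # 3 genes x 4 cells
    return make_counts([[5, 0, 1, 2], [0, 0, 0, 0], [3, 1, 0, 4]])
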