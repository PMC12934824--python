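import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from plaincell.io import ExpressionMatrix


def make_matrix(counts, cell_meta=None, gene_ids=None, cell_ids=None) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a dense array for tests."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cells = cell_ids if cell_ids is not None else [f"c{i}" for i in range(n_cells)]
    genes = gene_ids if gene_ids is not None else [f"g{j}" for j in range(n_genes)]
    meta = pd.DataFrame(cell_meta) if cell_meta is not None else None
    return ExpressionMatrix(sp.csr_matrix(counts), np.array(cells, dtype=object),
                            np.array(genes, dtype=object), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def three_program_matrix(rng):
    """90 cells x 60 genes, three cell types with disjoint planted markers."""
    n_per, n_genes = 30, 60
    markers = {"typeA": [0, 1], "typeB": [20, 21], "typeC": [40, 41]}
    rows, labels = [], []
    for t, (name, mk) in enumerate(markers.items()):
        lam = np.full(n_genes, 2.0)
        lam[mk] = 60.0
        rows.append(rng.poisson(lam, size=(n_per, n_genes)))
        labels += [name] * n_per
    return make_matrix(np.vstack(rows), {"cell_type": labels}), markers
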