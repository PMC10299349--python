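import numpy as np
import pytest
import scipy.sparse as sp

from markercover.cover import CoverConfig
from markercover.matrix import ExpressionMatrix, binarize


# The ABC micro-fixture: genes A, B, C over four cells of one class, with
# expression patterns A:{c1,c2,c3}, B:{c2,c3,c4}, C:{c1,c4}. All expected
# objectives asserted against it were frozen from exhaustive enumeration of
# every gene subset.
ABC_U = np.array(
    [  # cells x genes, gene order (A, B, C)
        [1, 0, 1],  # c1
        [1, 1, 0],  # c2
        [1, 1, 0],  # c3
        [0, 1, 1],  # c4
    ],
    dtype=np.int8,
)
ABC_W = np.array([0.3, 0.3, 0.5])
ABC_GENES = ["A", "B", "C"]


@pytest.fixture
def abc_instance():
    return ABC_U.copy(), ABC_W.copy()


@pytest.fixture
def abc_matrix():
    """The ABC fixture as a labeled two-class ExpressionMatrix.

    Class k holds the four ABC cells; a second class "other" of four cells
    expresses nothing, so every ABC gene is a perfect candidate for k.
    """
    counts = np.zeros((3, 8))
    counts[:, :4] = ABC_U.T  # genes x cells
    labels = np.array(["k"] * 4 + ["other"] * 4, dtype=object)
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(ABC_GENES, dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(1, 9)], dtype=object),
        labels=labels,
    )


def random_instance(rng, max_genes=12, max_cells=40):
    """A random covering instance for oracle-equivalence checks."""
    n_genes = int(rng.integers(1, max_genes + 1))
    n_cells = int(rng.integers(1, max_cells + 1))
    p = rng.uniform(0.1, 0.9)
    U = (rng.random((n_cells, n_genes)) < p).astype(np.int8)
    w = rng.uniform(0.01, 1.0, size=n_genes)
    depth = int(rng.integers(1, 4))
    alpha = float(rng.choice([0.0, 0.1, 0.25]))
    return U, w, CoverConfig(depth=depth, alpha=alpha)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(counts, gene_ids=None, cell_ids=None, labels=None):
    counts = np.asarray(counts, dtype=float)
    ng, nc = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(ng)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(nc)]
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
        labels=None if labels is None else np.array(labels, dtype=object),
    )


@pytest.fixture
def binary_of():
    def _make(counts, **kw):
        return binarize(make_matrix(counts, **kw), 0.0)
    return _make
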