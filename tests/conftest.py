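import numpy as np
import pytest

from markerpanels.singles import ClusterAssignment, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_matrix(values, gene_ids=None, cell_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cells = cell_ids or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells)


def make_clusters(labels, cell_ids=None) -> ClusterAssignment:
    cells = cell_ids or [f"c{i}" for i in range(len(labels))]
    return ClusterAssignment(dict(zip(cells, labels)))


@pytest.fixture
def clean_marker_fixture():
    """One gene cleanly marking the first 3 of 6 cells."""
    matrix = make_matrix([[5.0, 4.0, 3.0, 0.0, 0.0, 0.0]])
    clusters = make_clusters(["K", "K", "K", "C", "C", "C"])
    return matrix, clusters
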