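import numpy as np
import pytest

from prodis import FeatureTable, PairwiseMatrix


def random_dissimilarity(rng, n, has_query=False):
    """Random symmetric non-negative matrix with zero diagonal."""
    A = rng.random((n, n)) * 10.0
    M = (A + A.T) / 2.0
    np.fill_diagonal(M, 0.0)
    ids = [f"x{i}" for i in range(n)]
    return PairwiseMatrix(M, "dissimilarity", ids, has_query=has_query)


def random_similarity(rng, n, has_query=False):
    """Random symmetric similarity matrix whose diagonal is the row max."""
    A = rng.random((n, n))
    M = (A + A.T) / 2.0
    np.fill_diagonal(M, 1.5)
    ids = [f"x{i}" for i in range(n)]
    return PairwiseMatrix(M, "similarity", ids, has_query=has_query)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def collinear_table():
    """Three 1-D points at 0, 1 and 3 — every context is hand-enumerable."""
    return FeatureTable(ids=["a", "b", "c"], X=np.array([[0.0], [1.0], [3.0]]))


@pytest.fixture
def collinear_matrix(collinear_table):
    """Squared-Euclidean matrix of the collinear points: [[0,1,9],[1,0,4],[9,4,0]]."""
    from prodis import build_matrix

    return build_matrix(collinear_table, "sqeuclidean")
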