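import networkx as nx
import numpy as np
import pytest

from nbmda.io_formats import AssociationMatrix, DiseaseDAG


def brute_force_neighborhood(X, i, j):
    """Independent oracle: enumerate every length-3 path d_i - m_k - d_l - m_j.

    Collects the interior nodes as common neighbors, counts the network
    edges internal to that community, and sums the endpoint degrees, all on
    the matrix with the seed edge removed.
    """
    X = np.asarray(X).copy()
    X[i, j] = 0
    n_d, n_m = X.shape
    cn_m, cn_d = set(), set()
    for k in range(n_m):
        for l in range(n_d):
            if X[i, k] and X[l, k] and X[l, j]:
                cn_m.add(k)
                cn_d.add(l)
    lcl = sum(1 for l in cn_d for k in cn_m if X[l, k])
    degree_sum = int(X[i, :].sum() + X[:, j].sum())
    return cn_m, cn_d, lcl, degree_sum


def brute_force_cjc(X, i, j):
    cn_m, cn_d, lcl, deg = brute_force_neighborhood(X, i, j)
    if deg == 0:
        return 0.0
    return (len(cn_m) + len(cn_d)) * lcl / deg


def random_bipartite(rng, n_d, n_m, density):
    return (rng.random((n_d, n_m)) < density).astype(np.int8)


@pytest.fixture
def chain_dag():
    """C -> B -> A (edges child -> parent)."""
    return DiseaseDAG(nx.DiGraph([("C", "B"), ("B", "A")]))


@pytest.fixture
def diamond_dag():
    """C -> {B1, B2} -> A."""
    return DiseaseDAG(nx.DiGraph([("C", "B1"), ("C", "B2"), ("B1", "A"), ("B2", "A")]))


@pytest.fixture
def toy_assoc():
    """Three edges: (d1,m2), (d2,m2), (d2,m1) — one quadrangle around (d1,m1)."""
    A = np.array([[0, 1], [1, 1]], dtype=np.int8)
    return AssociationMatrix(A, ["d1", "d2"], ["m1", "m2"])
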