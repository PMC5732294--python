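import numpy as np
import pytest
import scipy.sparse as sp

from chd.connectome import ConnectomeGraph, synth_connectome
from chd.harmonics import harmonics_of


def graph_from_edges(n, edges):
    """Build a binary ConnectomeGraph from an explicit undirected edge list."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    i, j = edges[:, 0], edges[:, 1]
    a = sp.coo_matrix(
        (np.ones(2 * len(edges)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
    ).tocsr()
    a.data[:] = 1.0
    return ConnectomeGraph(adjacency=a, local_edges=np.sort(edges, axis=1))


def cycle_graph(n):
    return graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def path_graph(n):
    return graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])


@pytest.fixture(scope="session")
def k2():
    return graph_from_edges(2, [(0, 1)])


@pytest.fixture(scope="session")
def synth_graph_order2():
    return synth_connectome(2, 200, 0.5, seed=7)


@pytest.fixture(scope="session")
def basis_order2(synth_graph_order2):
    return harmonics_of(synth_graph_order2, "all")
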