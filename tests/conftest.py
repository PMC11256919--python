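import numpy as np
import pytest
import scipy.sparse as sp

from graphtucker.graphs import GraphSet, build_graph_set
from graphtucker.optimizer import TuckerModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_model(rng, shape, rank) -> TuckerModel:
    ny, nx, ng = shape
    ry, rx, rg = rank
    return TuckerModel(
        core=rng.uniform(size=(ry, rx, rg)),
        ay=rng.uniform(size=(ny, ry)),
        ax=rng.uniform(size=(nx, rx)),
        ag=rng.uniform(size=(ng, rg)),
    )


def random_gene_graph(rng, ng: int, n_edges: int):
    """Random simple undirected graph adjacency over ng genes."""
    n_edges = min(n_edges, ng * (ng - 1) // 2)
    adj = np.zeros((ng, ng))
    while adj.sum() < 2 * n_edges:
        i, j = rng.integers(ng, size=2)
        if i != j:
            adj[i, j] = adj[j, i] = 1.0
    from graphtucker.graphs import UndirectedGraph

    return UndirectedGraph(sp.csr_matrix(adj))


def dense_product_laplacian(gs: GraphSet) -> np.ndarray:
    """Explicit Kronecker-sum Laplacian matching C-order vectorization of
    a (ny, nx, ng) tensor — the brute-force oracle for the regularizer."""
    ly, lx, lg = [np.asarray(l.todense()) for l in gs.laplacians()]
    ny, nx, ng = ly.shape[0], lx.shape[0], lg.shape[0]
    iy, ix, ig = np.eye(ny), np.eye(nx), np.eye(ng)
    return (
        np.kron(ly, np.kron(ix, ig))
        + np.kron(iy, np.kron(lx, ig))
        + np.kron(iy, np.kron(ix, lg))
    )


@pytest.fixture
def tiny_problem(rng):
    """Small masked problem with graphs for optimizer tests."""
    shape, rank = (4, 5, 3), (2, 2, 2)
    t = rng.uniform(size=shape)
    m = (rng.uniform(size=shape) < 0.7).astype(float)
    network = random_gene_graph(rng, shape[2], 2)
    gs = build_graph_set(shape, network)
    model = random_model(rng, shape, rank)
    return t, m, model, gs
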