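"""Spatial chain graphs, the gene interaction network, and the
Cartesian-product-graph regularizer.

The regularizer couples the three tensor axes through the Laplacian of the
Cartesian product of three graphs: two unweighted chain (path) graphs along
the y and x spot coordinates, and a gene interaction network (e.g. a
protein-protein interaction network).  The Laplacian of a Cartesian product
graph is the Kronecker sum of the factor Laplacians, so the quadratic form
vec(T)ᵀ (Ly ⊕ Lx ⊕ Lg) vec(T) decomposes into one n-mode-product term per
axis and the product Laplacian never has to be materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .tensor_algebra import nmode_product, unfold

__all__ = [
    "UndirectedGraph",
    "GraphSet",
    "build_chain_graph",
    "laplacian",
    "load_gene_network",
    "build_graph_set",
    "product_quadratic_form",
]


@dataclass
class UndirectedGraph:
    """An undirected graph aligned to one tensor axis.

    ``adjacency`` is symmetric, nonnegative, with a zero diagonal;
    ``node_ids`` (optional) carries identifiers in axis order.
    """

    adjacency: sp.csr_matrix
    node_ids: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def validate(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        if a.nnz and a.data.min() < 0:
            raise ValueError("adjacency must be nonnegative")


@dataclass
class GraphSet:
    """Laplacians for the three tensor axes, in axis order (y, x, gene)."""

    ly: sp.csr_matrix
    lx: sp.csr_matrix
    lg: sp.csr_matrix

    def laplacians(self) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
        return (self.ly, self.lx, self.lg)

    def degree_adjacency_parts(self):
        """Per mode: (D, W) with L = D − W, both nonnegative."""
        out = []
        for lap in self.laplacians():
            d = sp.diags(lap.diagonal())
            w = (d - lap).tocsr()
            out.append((d.tocsr(), w))
        return out


def build_chain_graph(n: int) -> UndirectedGraph:
    """Unweighted path graph on ``n`` nodes (node i adjacent to i±1)."""
    if n < 1:
        raise ValueError(f"chain graph needs at least one node, got {n}")
    if n == 1:
        return UndirectedGraph(sp.csr_matrix((1, 1)))
    ones = np.ones(n - 1)
    adj = sp.diags([ones, ones], [-1, 1], format="csr")
    return UndirectedGraph(adj)


def laplacian(g: UndirectedGraph) -> sp.csr_matrix:
    """Combinatorial Laplacian L = D − W (symmetric, PSD, zero row sums)."""
    w = g.adjacency
    d = sp.diags(np.asarray(w.sum(axis=1)).ravel())
    return (d - w).tocsr()


def load_gene_network(
    edges,
    genes: list[str],
    weighted: bool = False,
) -> UndirectedGraph:
    """Restrict an edge list to the tensor's gene axis.

    Parameters
    ----------
    edges : path to a TSV (columns gene_a, gene_b [, weight]; header
        optional, lines starting with ``#`` ignored) or an iterable of
        ``(gene_a, gene_b)`` / ``(gene_a, gene_b, weight)`` tuples.
    genes : gene identifiers in tensor-axis order; the graph has exactly
        these nodes.  Genes absent from the network are isolated.
    weighted : keep edge weights (duplicates summed).  Default binarizes —
        any number of evidence lines collapses to weight 1.

    Self-loops are dropped and duplicate/reversed edges deduplicated.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    index = {g: i for i, g in enumerate(genes)}
    if len(index) != len(genes):
        raise ValueError("gene identifiers must be unique")

    if isinstance(edges, (str, Path)):
        edges = _read_edge_tsv(Path(edges))

    n = len(genes)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for rec in edges:
        a, b = rec[0], rec[1]
        w = float(rec[2]) if len(rec) > 2 else 1.0
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None or ia == ib:
            continue
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    adj = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    adj.sum_duplicates()
    if not weighted:
        adj.data[:] = 1.0
    return UndirectedGraph(adj, node_ids=list(genes))


def _read_edge_tsv(path: Path):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno + 1}: expected >= 2 columns")
            if lineno == 0 and _looks_like_header(parts):
                continue
            records.append(tuple(parts[:3]))
    return records


def _looks_like_header(parts: list[str]) -> bool:
    first = parts[0].lower()
    return first in {"gene_a", "gene1", "source", "genea", "gene"}


def build_graph_set(
    shape: tuple[int, int, int], gene_network: UndirectedGraph | None = None
) -> GraphSet:
    """Chain Laplacians for the spatial axes plus the gene-network
    Laplacian (edgeless if no network is given)."""
    ny, nx, ng = shape
    ly = laplacian(build_chain_graph(ny))
    lx = laplacian(build_chain_graph(nx))
    if gene_network is None:
        lg = sp.csr_matrix((ng, ng))
    else:
        if gene_network.n_nodes != ng:
            raise ValueError(
                f"gene network has {gene_network.n_nodes} nodes, tensor has "
                f"{ng} genes"
            )
        lg = laplacian(gene_network)
    return GraphSet(ly=ly, lx=lx, lg=lg)


def product_quadratic_form(t: np.ndarray, gs: GraphSet) -> float:
    """vec(t)ᵀ (Ly ⊕ Lx ⊕ Lg) vec(t), without forming the Kronecker sum.

    Equal to the sum over modes of ⟨t, t ×_mode L_mode⟩; zero exactly when
    ``t`` is constant along every connected component of every mode graph.
    """
    t = np.asarray(t)
    total = 0.0
    for mode, lap in enumerate(gs.laplacians()):
        if lap.shape[0] != t.shape[mode]:
            raise ValueError(
                f"Laplacian for mode {mode} has size {lap.shape[0]}, tensor "
                f"has {t.shape[mode]}"
            )
        u = unfold(t, mode)
        total += float(np.sum(u * (lap @ u)))
    # clip tiny negative round-off: the form is PSD
    return max(total, 0.0)
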