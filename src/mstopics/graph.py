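"""Geometric similarity graph construction.

From document vectors to a sparsified weighted graph in two steps:

1. ``similarity_matrix`` — pairwise cosine similarity, converted to a
   distance ``D = 1 - S_cos``, max-normalised over off-diagonal entries to
   ``D_hat`` and flipped back to a normalised similarity
   ``S_hat = 1 - D_hat`` with entries in [0, 1] (the most distant pair of
   documents attains exactly 0).
2. ``mst_knn`` — the union of the minimum spanning tree of ``D_hat``
   (global connectivity) with each node's k nearest neighbours (local
   geometry), Hadamard-weighted by ``S_hat``.

The MST is computed by Kruskal's algorithm with a deterministic tie-break
(stable sort on distance, then smaller node index, then larger), so the
graph is bit-reproducible even under tied distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embedding import DocVectorSet

__all__ = [
    "SimilarityMatrix",
    "WeightedGraph",
    "similarity_matrix",
    "mst_knn",
    "write_edge_list",
    "write_graphml",
]

DEFAULT_K = 13


@dataclass
class SimilarityMatrix:
    """Normalised pairwise document similarity, entries in [0, 1]."""

    S_hat: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        S = np.asarray(self.S_hat, dtype=float)
        if S.shape[0] != S.shape[1] or S.shape[0] != len(self.ids):
            raise ValueError("S_hat must be square and match ids")
        self.S_hat = S

    @property
    def distances(self) -> np.ndarray:
        return 1.0 - self.S_hat


@dataclass
class WeightedGraph:
    """Sparsified weighted adjacency with its binary edge mask."""

    A: np.ndarray
    edge_mask: np.ndarray
    k: int
    ids: list[str]

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.edge_mask, 1)))

    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=1)

    def is_connected(self) -> bool:
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(self.A > 0, directed=False)
        return bool(n_comp == 1)


def similarity_matrix(vectors: DocVectorSet) -> SimilarityMatrix:
    """Normalised cosine similarity matrix of a document vector set.

    Raises if any vector has zero norm (naming the document).  If all
    pairwise distances are zero the geometry is degenerate and ``S_hat``
    is defined as all ones, with a warning.
    """
    X = vectors.vectors
    if X.shape[0] < 2:
        raise ValueError("need at least 2 documents")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm vector for document {vectors.ids[zero[0]]!r}")
    Xn = X / norms[:, None]
    S_cos = np.clip(Xn @ Xn.T, -1.0, 1.0)
    D_cos = 1.0 - S_cos
    np.fill_diagonal(D_cos, 0.0)
    off_max = D_cos.max()
    if off_max <= 0.0:
        warnings.warn("all pairwise distances are zero; S_hat set to all ones")
        S_hat = np.ones_like(D_cos)
    else:
        S_hat = 1.0 - D_cos / off_max
    S_hat = np.clip((S_hat + S_hat.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S_hat, 1.0)
    return SimilarityMatrix(S_hat=S_hat, ids=list(vectors.ids))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def _kruskal_mst(D: np.ndarray) -> list[tuple[int, int]]:
    """MST edges of the dense distance matrix by Kruskal with a stable
    (distance, smaller index, larger index) tie-break."""
    n = D.shape[0]
    iu, ju = np.triu_indices(n, 1)
    order = np.lexsort((ju, iu, D[iu, ju]))
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        if uf.union(i, j):
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return edges


def mst_knn(S: SimilarityMatrix, k: int = DEFAULT_K) -> WeightedGraph:
    """Sparsify a similarity matrix to the MST-kNN graph.

    The edge set is the union of the minimum spanning tree of the
    normalised distances with each node's ``k`` nearest neighbours (self
    excluded; all neighbours tied at the k-th distance are included; the
    union of directed neighbourhoods is symmetrised).  Kept edges carry
    the ``S_hat`` weight exactly.
    """
    n = len(S.ids)
    if not 0 <= k <= n - 1:
        raise ValueError(f"k must be in [0, {n - 1}], got {k}")
    D = S.distances.copy()
    np.fill_diagonal(D, np.inf)
    mask = np.zeros((n, n), dtype=np.int8)
    for i, j in _kruskal_mst(np.where(np.isinf(D), 0.0, D)):
        mask[i, j] = mask[j, i] = 1
    if k > 0:
        kth = np.partition(D, k - 1, axis=1)[:, k - 1]
        near = D <= kth[:, None]  # includes all ties at the k-th distance
        mask |= near.astype(np.int8)
        mask |= near.T.astype(np.int8)
    np.fill_diagonal(mask, 0)
    A = mask * S.S_hat
    np.fill_diagonal(A, 0.0)
    return WeightedGraph(A=A, edge_mask=mask, k=k, ids=list(S.ids))


def write_edge_list(G: WeightedGraph, path: str | Path) -> None:
    """Write the weighted edge list as tab-separated (id_u, id_v, weight)."""
    iu, ju = np.triu_indices(G.n_nodes, 1)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id_u\tid_v\tweight\n")
        for i, j in zip(iu, ju):
            if G.edge_mask[i, j]:
                fh.write(f"{G.ids[i]}\t{G.ids[j]}\t{G.A[i, j]:.12g}\n")


def read_edge_list(path: str | Path) -> WeightedGraph:
    """Read a graph written by :func:`write_edge_list`."""
    ids: list[str] = []
    index: dict[str, int] = {}
    rows: list[tuple[str, str, float]] = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("id_u"):
            raise ValueError("not an edge-list file")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            rows.append((u, v, float(w)))
            for x in (u, v):
                if x not in index:
                    index[x] = len(ids)
                    ids.append(x)
    n = len(ids)
    A = np.zeros((n, n))
    for u, v, w in rows:
        i, j = index[u], index[v]
        A[i, j] = A[j, i] = w
    mask = (A > 0).astype(np.int8)
    return WeightedGraph(A=A, edge_mask=mask, k=-1, ids=ids)


def write_graphml(G: WeightedGraph, path: str | Path) -> None:
    """Export the graph as GraphML (via networkx)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(G.ids)
    iu, ju = np.triu_indices(G.n_nodes, 1)
    for i, j in zip(iu, ju):
        if G.edge_mask[i, j]:
            g.add_edge(G.ids[i], G.ids[j], weight=float(G.A[i, j]))
    nx.write_graphml(g, str(path))
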