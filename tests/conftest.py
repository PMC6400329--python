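"""Shared fixtures: small reference graphs, planted fixtures and the
exhaustive set-partition oracle for the stability objective."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mstopics.graph import WeightedGraph
from mstopics.markov_stability import (
    diffusion_operator,
    stability_matrix,
    transition_kernel,
    _r_value,
)


def make_graph(A: np.ndarray) -> WeightedGraph:
    A = np.asarray(A, dtype=float)
    return WeightedGraph(
        A=A,
        edge_mask=(A > 0).astype(np.int8),
        k=-1,
        ids=[f"n{i}" for i in range(A.shape[0])],
    )


def clique_adjacency(groups: list[list[int]], n: int) -> np.ndarray:
    A = np.zeros((n, n))
    for g in groups:
        for i, j in itertools.combinations(g, 2):
            A[i, j] = A[j, i] = 1.0
    return A


def set_partitions(n: int):
    """All set partitions of range(n) as membership vectors (restricted
    growth strings)."""

    def rec(prefix: list[int], maxv: int):
        if len(prefix) == n:
            yield np.array(prefix, dtype=np.intp)
            return
        for v in range(maxv + 2):
            yield from rec(prefix + [v], max(maxv, v))

    yield from rec([], -1)


def exhaustive_max_stability(op, t: float) -> float:
    """Brute-force maximum of r(t, H) over every set partition (N <= 8)."""
    B = stability_matrix(op, transition_kernel(op, t))
    Bs = (B + B.T) / 2.0
    return max(_r_value(Bs, m) for m in set_partitions(op.n_nodes))


@pytest.fixture(scope="session")
def small_graphs() -> dict[str, WeightedGraph]:
    """Connected reference graphs with at most 8 nodes."""
    graphs: dict[str, np.ndarray] = {}
    barbell = clique_adjacency([[0, 1, 2, 3], [4, 5, 6, 7]], 8)
    barbell[3, 4] = barbell[4, 3] = 1.0
    graphs["barbell8"] = barbell
    K4 = np.ones((4, 4)) - np.eye(4)
    graphs["K4"] = K4
    path = np.zeros((5, 5))
    for i in range(4):
        path[i, i + 1] = path[i + 1, i] = 1.0
    graphs["path5"] = path
    star = np.zeros((6, 6))
    star[0, 1:] = star[1:, 0] = 1.0
    graphs["star6"] = star
    cycle = np.zeros((7, 7))
    for i in range(7):
        cycle[i, (i + 1) % 7] = cycle[(i + 1) % 7, i] = 1.0
    graphs["cycle7"] = cycle
    weighted = clique_adjacency([[0, 1, 2], [3, 4, 5]], 6) * 1.0
    weighted[2, 3] = weighted[3, 2] = 0.25
    graphs["weighted_dumbbell6"] = weighted
    return {name: make_graph(A) for name, A in graphs.items()}


@pytest.fixture(scope="session")
def two_cliques_graph() -> WeightedGraph:
    """Two disconnected 3-cliques (no zero-degree nodes, two components)."""
    return make_graph(clique_adjacency([[0, 1, 2], [3, 4, 5]], 6))


@pytest.fixture(scope="session")
def planted_graph():
    from mstopics.synthetic import generate_multiscale_graph

    return generate_multiscale_graph(seed=1)


@pytest.fixture(scope="session")
def topic_corpus():
    """Default planted-topic corpus, preprocessed, with both label maps."""
    import mstopics as m

    docs, sub, sup = m.generate_corpus(m.TopicSpec(seed=3))
    m.preprocess_documents(docs)
    return docs, sub, sup


@pytest.fixture(scope="session")
def random_vector_set():
    import mstopics as m

    rng = np.random.default_rng(42)
    X = rng.normal(size=(100, 16))
    return m.DocVectorSet(ids=[f"d{i:03d}" for i in range(100)], vectors=X)
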