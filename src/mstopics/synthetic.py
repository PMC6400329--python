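"""Synthetic corpora and graphs with planted multiscale structure.

The corpus generator emulates the structure of collections of short, noisy
free-text reports drawn from a quasi-hierarchical set of topics: sub-themes
(each with its own keyword vocabulary) nest into themes (which contribute a
shared keyword pool), on top of a common background vocabulary.  Every
stage of the pipeline is therefore testable end to end without external
data, with known labels at two resolutions.

Vocabulary items are pronounceable pseudo-words (``"sup0sub1kw03"``) that
pass through stemming and stop-word removal unchanged, isolating clustering
behaviour from linguistic preprocessing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import Document
from .graph import WeightedGraph

__all__ = ["TopicSpec", "generate_corpus", "generate_multiscale_graph"]


@dataclass
class TopicSpec:
    """Parameters of the planted-topic corpus.

    Defaults give 2 themes x 2 sub-themes x 25 documents = 100 short
    documents, with roughly half of each document's tokens drawn from its
    topic keywords and the rest from a shared background vocabulary.
    """

    n_super: int = 2
    subs_per_super: int = 2
    docs_per_sub: int = 25
    keywords_per_sub: int = 10
    shared_super_keywords: int = 8
    background_vocab: int = 120
    doc_length: int = 40
    keyword_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_super", "subs_per_super", "docs_per_sub", "keywords_per_sub",
            "shared_super_keywords", "background_vocab", "doc_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.keyword_rate <= 1.0:
            raise ValueError("keyword_rate must be in (0, 1]")


def generate_corpus(
    spec: TopicSpec,
) -> tuple[list[Document], dict[str, str], dict[str, str]]:
    """Generate a planted-topic corpus.

    Returns ``(documents, sub_labels, super_labels)`` where the label maps
    are keyed by document id.  Each document draws ``doc_length`` tokens:
    with probability ``keyword_rate`` from its sub-topic keywords united
    with its super-topic shared keywords, otherwise from the background
    vocabulary.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    background = [f"bg{j:03d}wd" for j in range(spec.background_vocab)]
    docs: list[Document] = []
    sub_labels: dict[str, str] = {}
    super_labels: dict[str, str] = {}
    for s in range(spec.n_super):
        shared = [f"sup{s}shared{j:02d}" for j in range(spec.shared_super_keywords)]
        for b in range(spec.subs_per_super):
            sub_kw = [
                f"sup{s}sub{b}kw{j:02d}" for j in range(spec.keywords_per_sub)
            ]
            topical = sub_kw + shared
            for d in range(spec.docs_per_sub):
                doc_id = f"doc-s{s}-b{b}-{d:03d}"
                from_topic = rng.random(spec.doc_length) < spec.keyword_rate
                words = [
                    topical[rng.integers(len(topical))]
                    if t
                    else background[rng.integers(len(background))]
                    for t in from_topic
                ]
                docs.append(Document(id=doc_id, text=" ".join(words),
                                     category=f"super{s}"))
                sub_labels[doc_id] = f"sub{s}.{b}"
                super_labels[doc_id] = f"super{s}"
    return docs, sub_labels, super_labels


def generate_multiscale_graph(
    n_cliques: int = 4,
    clique_size: int = 8,
    n_groups: int = 2,
    p_in: float = 1.0,
    p_between: float = 1.0,
    w_in: float = 1.0,
    w_mid: float = 0.3,
    w_out: float = 0.05,
    seed: int = 0,
) -> tuple[WeightedGraph, np.ndarray, np.ndarray]:
    """Weighted graph with two planted scales of community structure.

    ``n_cliques`` cliques of ``clique_size`` nodes are internally wired at
    weight ``w_in`` (each internal edge present with probability ``p_in``);
    cliques are assigned round-robin to ``n_groups`` groups; node pairs in
    different cliques of the same group connect with probability
    ``p_between`` at weight ``w_mid``; pairs across groups at ``w_out``.
    Requires ``w_in > w_mid > w_out >= 0``.  If ``w_out = 0`` (or sampling)
    leaves the graph disconnected, a minimal set of epsilon-weight edges is
    added with a warning so the diffusion process is well defined.

    Returns ``(graph, clique_labels, group_labels)``.
    """
    if not (w_in > w_mid > w_out >= 0):
        raise ValueError("weights must satisfy w_in > w_mid > w_out >= 0")
    rng = np.random.default_rng(seed)
    n = n_cliques * clique_size
    clique_labels = np.repeat(np.arange(n_cliques), clique_size)
    group_labels = clique_labels % n_groups
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if clique_labels[i] == clique_labels[j]:
                w, p = w_in, p_in
            elif group_labels[i] == group_labels[j]:
                w, p = w_mid, p_between
            else:
                w, p = w_out, p_between
            if w > 0 and rng.random() < p:
                A[i, j] = A[j, i] = w
    # connectivity repair with epsilon edges between components
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(A > 0, directed=False)
    if n_comp > 1:
        eps = max(w_out, 1e-3 * w_mid)
        warnings.warn(
            f"graph had {n_comp} components; adding {n_comp - 1} "
            f"epsilon-weight ({eps:g}) bridging edges"
        )
        reps = [int(np.flatnonzero(comp == c)[0]) for c in range(n_comp)]
        for a, b in zip(reps, reps[1:]):
            A[a, b] = A[b, a] = eps
    ids = [f"n{i:03d}" for i in range(n)]
    mask = (A > 0).astype(np.int8)
    return WeightedGraph(A=A, edge_mask=mask, k=-1, ids=ids), clique_labels, group_labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    """Write an id -> label map as a two-column CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        for doc_id, lab in labels.items():
            writer.writerow([doc_id, lab])
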