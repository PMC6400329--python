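"""Scoring of partitions: intrinsic topic coherence and label agreement.

Intrinsic coherence uses pointwise mutual information between word pairs,
with word and pair probabilities estimated from document frequencies over
the analysis corpus:

    PMI(w1, w2) = log[ P(w1 w2) / (P(w1) P(w2)) ]

(natural log; a pair co-occurs if both words appear anywhere in the same
document).  The aggregate score of a partition is the cluster-size-weighted
average, over clusters, of the median PMI among all pairs of the cluster's
top words.

Agreement with reference labels uses the normalised mutual information
NMI = I(C,D) / sqrt(H(C) H(D)), and cluster-by-category contingency tables
standardised against the fixed-margin (hypergeometric) independence null.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .markov_stability import Partition, _contingency
from .preprocess import Document, ngram_frequencies

logger = logging.getLogger(__name__)

__all__ = [
    "WordStats",
    "ContingencyReport",
    "build_word_stats",
    "pmi",
    "aggregate_pmi",
    "nmi",
    "contingency_zscores",
    "cluster_summaries",
    "sankey_links",
]


@dataclass
class WordStats:
    """Document-frequency statistics for PMI estimation."""

    doc_freq: dict[str, int]
    pair_doc_freq: dict[tuple[str, str], int]
    n_docs: int

    def pair_count(self, w1: str, w2: str) -> int:
        if w1 == w2:
            return self.doc_freq.get(w1, 0)
        key = (w1, w2) if w1 < w2 else (w2, w1)
        return self.pair_doc_freq.get(key, 0)


def build_word_stats(docs: Sequence[Document], field: str = "tokens") -> WordStats:
    """Count document and pair document frequencies over a token field."""
    doc_freq: Counter[str] = Counter()
    pair_freq: Counter[tuple[str, str]] = Counter()
    for doc in docs:
        words = sorted(set(getattr(doc, field)))
        doc_freq.update(words)
        pair_freq.update(combinations(words, 2))
    return WordStats(
        doc_freq=dict(doc_freq), pair_doc_freq=dict(pair_freq), n_docs=len(docs)
    )


def pmi(stats: WordStats, w1: str, w2: str, floor: float | None = None) -> float:
    """Pointwise mutual information of a word pair (document co-occurrence).

    Pairs that never co-occur return the configured ``floor`` (default
    ``-log(n_docs)``, the magnitude scale of the smallest observable
    co-occurrence probability).  Unseen words raise, naming the word.
    """
    for w in (w1, w2):
        if stats.doc_freq.get(w, 0) == 0:
            raise ValueError(f"word not in corpus statistics: {w!r}")
    n = stats.n_docs
    co = stats.pair_count(w1, w2)
    if co == 0:
        return -math.log(n) if floor is None else floor
    p1 = stats.doc_freq[w1] / n
    p2 = stats.doc_freq[w2] / n
    return math.log((co / n) / (p1 * p2))


def _top_words(
    docs: Sequence[Document], top_n: int, field: str = "tokens"
) -> list[str]:
    """Top words of a document group by within-group document frequency,
    ties broken lexicographically."""
    freq: Counter[str] = Counter()
    for doc in docs:
        freq.update(set(getattr(doc, field)))
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return [w for w, _ in ranked[:top_n]]


def aggregate_pmi(
    part: Partition,
    docs: Sequence[Document],
    stats: WordStats | None = None,
    top_n: int = 10,
    floor: float | None = None,
    field: str = "tokens",
) -> float:
    """Cluster-size-weighted average of per-cluster median top-word PMI.

    For each cluster, the ``top_n`` most frequent words within the cluster
    form the set S_i; the cluster's score is the median PMI over all
    unordered pairs in S_i, and the partition's score is
    ``sum_i (n_i / N) * median_i``.  A cluster with fewer than two distinct
    words contributes the floor value (with a warning).
    """
    if top_n < 2:
        raise ValueError("top_n must be at least 2")
    if part.n_nodes != len(docs):
        raise ValueError("partition size does not match document count")
    if stats is None:
        stats = build_word_stats(docs, field)
    floor_val = -math.log(stats.n_docs) if floor is None else floor
    total = 0.0
    N = len(docs)
    for c in range(part.n_communities):
        members = [docs[i] for i in np.flatnonzero(part.membership == c)]
        words = _top_words(members, top_n, field)
        if len(words) < 2:
            logger.warning(
                "cluster %d has fewer than 2 distinct words; using floor", c
            )
            med = floor_val
        else:
            scores = [
                pmi(stats, w1, w2, floor=floor_val)
                for w1, w2 in combinations(words, 2)
            ]
            med = float(np.median(scores))
        total += (len(members) / N) * med
    return total


def nmi(C: Partition, D: Partition) -> float:
    """Normalised mutual information, geometric normalisation.

    ``I(C,D) / sqrt(H(C) H(D))`` in [0, 1]; equal to 1 iff the partitions
    coincide up to relabelling.  Raises for a zero-entropy (trivial)
    partition, where the score is undefined.
    """
    if C.n_nodes != D.n_nodes:
        raise ValueError("partitions are over different node sets")
    counts = _contingency(C.membership, D.membership)
    return nmi_from_counts(counts)


def nmi_from_counts(counts: np.ndarray) -> float:
    """NMI evaluated directly on a contingency table of counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n
    pc = p.sum(axis=1)
    pd = p.sum(axis=0)
    hc = -np.sum(pc[pc > 0] * np.log(pc[pc > 0]))
    hd = -np.sum(pd[pd > 0] * np.log(pd[pd > 0]))
    if hc <= 0 or hd <= 0:
        raise ValueError("NMI undefined for trivial partition")
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (pc[:, None] * pd[None, :])[nz])))
    return min(1.0, max(0.0, mi / math.sqrt(hc * hd)))


@dataclass
class ContingencyReport:
    """Cluster-by-category counts, hypergeometric z-scores and NMI."""

    counts: np.ndarray
    zscores: np.ndarray
    nmi: float
    cluster_sizes: np.ndarray = None
    category_sizes: np.ndarray = None
    categories: list[str] | None = None


def contingency_zscores(
    C: Partition, labels: Sequence[str] | Mapping[int, str]
) -> ContingencyReport:
    """Standardised contingency table against the fixed-margin null.

    Under the hypergeometric null (cluster and category margins fixed,
    assignments exchangeable), cell (c, k) has expectation
    ``E = n_c n_k / N`` and variance
    ``E (1 - n_c/N) (N - n_k)/(N - 1)``; the z-score is ``(n - E)/sd``
    (0 where the variance vanishes).
    """
    if isinstance(labels, Mapping):
        labels = [labels[i] for i in range(C.n_nodes)]
    if len(labels) != C.n_nodes:
        raise ValueError("every node must be labelled")
    D = Partition.from_labels(labels)
    cats: list[str] = []
    seen = set()
    for l in labels:
        if l not in seen:
            seen.add(l)
            cats.append(l)
    counts = _contingency(C.membership, D.membership)
    N = counts.sum()
    nc = counts.sum(axis=1, keepdims=True)
    nk = counts.sum(axis=0, keepdims=True)
    E = nc * nk / N
    var = E * (1 - nc / N) * (N - nk) / (N - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (counts - E) / np.sqrt(var), 0.0)
    try:
        score = nmi_from_counts(counts)
    except ValueError:
        score = float("nan")
    return ContingencyReport(
        counts=counts,
        zscores=z,
        nmi=score,
        cluster_sizes=nc.ravel(),
        category_sizes=nk.ravel(),
        categories=cats,
    )


def cluster_summaries(
    part: Partition,
    docs: Sequence[Document],
    n_top: int = 20,
    n_range: tuple[int, int] = (1, 3),
) -> list[list[tuple[tuple[str, ...], int]]]:
    """Per-cluster top n-grams over ``summary_tokens``, for downstream
    word-cloud rendering.  Empty clusters yield empty lists."""
    if part.n_nodes != len(docs):
        raise ValueError("partition size does not match document count")
    out = []
    for c in range(part.n_communities):
        members = [docs[i] for i in np.flatnonzero(part.membership == c)]
        grams = ngram_frequencies(members, n_range)
        out.append(list(grams.items())[:n_top])
    return out


def sankey_links(
    A: Partition, B: Partition, names_a: str = "A", names_b: str = "B"
) -> list[dict]:
    """Flow triples (source, target, value) between two partitions, for
    external Sankey rendering."""
    counts = _contingency(A.membership, B.membership)
    links = []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            v = int(counts[i, j])
            if v:
                links.append(
                    {"source": f"{names_a}{i}", "target": f"{names_b}{j}", "value": v}
                )
    return links


def write_report(report: dict, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
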