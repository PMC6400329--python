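"""Document vector representations.

Two routes to a fixed-dimension vector per document:

* **PV-DBOW** (distributed bag of words paragraph vectors): each document
  owns a trainable d-dimensional vector optimised, via negative sampling,
  to predict the words the document contains.  Implemented here directly
  in numpy — stochastic gradient descent with a linearly decaying learning
  rate, a unigram^0.75 noise distribution and optional subsampling of
  frequent words.  Training is sequential and bit-reproducible for a fixed
  seed.
* **TF-iDF** bag-of-words vectors, as the sparse baseline.

Embedding quality is benchmarked by the centroid procedure: for each
labelled category, rank all documents by cosine similarity to the category
centroid and count how many of the nearest ``per_centroid`` documents carry
that label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "DocVectorSet",
    "PVDBOWModel",
    "train_embedding",
    "infer_vectors",
    "tfidf_vectors",
    "centroid_benchmark",
]


@dataclass
class EmbeddingConfig:
    """Hyper-parameters of the embedding stage.

    The PV-DBOW defaults are the optimised set used for the full-scale
    analysis: 300 dimensions, 10 epochs, window 15, minimum count 5,
    5 negative samples, subsampling threshold 1e-3.  (The window parameter
    is accepted for interface compatibility; pure PV-DBOW predicts words
    from the document vector alone, so no context window enters the
    objective.)
    """

    method: str = "pvdbow"
    dim: int = 300
    epochs: int = 10
    window: int = 15
    min_count: int = 5
    negative: int = 5
    subsample: float = 0.001
    seed: int = 0
    alpha: float = 0.025
    min_alpha: float = 1e-4
    infer_epochs: int = 50
    smooth_idf: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("pvdbow", "tfidf"):
            raise ValueError(f"unknown embedding method: {self.method!r}")
        for name in ("dim", "epochs", "window", "min_count", "negative"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.subsample <= 1.0:
            raise ValueError("subsample must be in [0, 1]")


@dataclass
class DocVectorSet:
    """N documents as rows of an N x d real matrix."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 and len(self.ids) > 0:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("row count must equal id count")
        if self.vectors.size and not np.isfinite(self.vectors).all():
            raise ValueError("vectors contain NaN or infinite entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.vectors, index=self.ids)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


@dataclass
class PVDBOWModel:
    """A trained PV-DBOW model: vocabulary, word output weights and the
    document vectors learned during training."""

    cfg: EmbeddingConfig
    vocab: dict[str, int]
    word_vectors: np.ndarray  # V x d output weights
    doc_vectors: np.ndarray  # n_train x d
    noise_cdf: np.ndarray = field(repr=False, default=None)
    keep_prob: np.ndarray = field(repr=False, default=None)

    def infer_vector(self, tokens: Sequence[str], seed: int | None = None) -> np.ndarray:
        """Infer a vector for a new document by gradient descent on a fresh
        document vector with frozen word weights.  Deterministic: the random
        stream is seeded from the model seed (or ``seed``) only, so identical
        token lists always yield identical vectors."""
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
        d = cfg.dim
        vec = (rng.random(d) - 0.5) / d
        idx = np.array([self.vocab[t] for t in tokens if t in self.vocab], dtype=np.intp)
        if idx.size == 0:
            logger.warning("document has no in-vocabulary tokens; returning prior vector")
            return vec
        alphas = np.linspace(cfg.alpha, cfg.min_alpha, cfg.infer_epochs)
        for alpha in alphas:
            for w in idx:
                negs = self._draw_negatives(rng, w)
                _sgd_step(vec, self.word_vectors, w, negs, alpha, train_words=False)
        return vec

    def _draw_negatives(self, rng: np.random.Generator, target: int) -> np.ndarray:
        negs = np.searchsorted(self.noise_cdf, rng.random(self.cfg.negative))
        return negs[negs != target]


def _sgd_step(
    doc_vec: np.ndarray,
    W: np.ndarray,
    target: int,
    negs: np.ndarray,
    alpha: float,
    train_words: bool = True,
) -> None:
    """One negative-sampling update: push the document vector towards the
    target word's output vector and away from the sampled noise words."""
    rows = np.concatenate(([target], negs))
    labels = np.zeros(len(rows))
    labels[0] = 1.0
    Wr = W[rows]
    g = (labels - _sigmoid(Wr @ doc_vec)) * alpha
    grad_doc = g @ Wr
    if train_words:
        W[rows] += np.outer(g, doc_vec)
    doc_vec += grad_doc


def train_embedding(
    corpus: Sequence[Sequence[str]], cfg: EmbeddingConfig
) -> PVDBOWModel:
    """Train a PV-DBOW model on a tokenised corpus.

    Reproducible for a fixed ``cfg.seed`` (training is single-threaded and
    sequential).  Raises on an empty corpus.
    """
    if len(corpus) == 0:
        raise ValueError("empty training corpus")
    if cfg.method != "pvdbow":
        raise ValueError("train_embedding requires method='pvdbow'")
    counts: dict[str, int] = {}
    for doc in corpus:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_words = sorted(w for w, c in counts.items() if c >= cfg.min_count)
    if not vocab_words:
        raise ValueError(
            f"no token reaches min_count={cfg.min_count}; vocabulary is empty"
        )
    vocab = {w: i for i, w in enumerate(vocab_words)}
    freq = np.array([counts[w] for w in vocab_words], dtype=float)

    noise = freq ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    total = freq.sum()
    if cfg.subsample > 0:
        frac = freq / total
        keep = np.minimum(1.0, np.sqrt(cfg.subsample / frac) + cfg.subsample / frac)
    else:
        keep = np.ones_like(freq)

    rng = np.random.default_rng(cfg.seed)
    d = cfg.dim
    n_docs = len(corpus)
    doc_vecs = (rng.random((n_docs, d)) - 0.5) / d
    W = np.zeros((len(vocab), d))
    doc_idx = [
        np.array([vocab[t] for t in doc if t in vocab], dtype=np.intp)
        for doc in corpus
    ]
    model = PVDBOWModel(cfg, vocab, W, doc_vecs, noise_cdf=noise_cdf, keep_prob=keep)
    alphas = np.linspace(cfg.alpha, cfg.min_alpha, cfg.epochs)
    for alpha in alphas:
        for di in range(n_docs):
            idx = doc_idx[di]
            if idx.size == 0:
                continue
            kept = idx[rng.random(idx.size) < keep[idx]]
            vec = doc_vecs[di]
            for w in kept:
                negs = model._draw_negatives(rng, w)
                _sgd_step(vec, W, w, negs, alpha, train_words=True)
    return model


def infer_vectors(
    model: PVDBOWModel,
    docs: Sequence[Sequence[str]],
    ids: Sequence[str] | None = None,
) -> DocVectorSet:
    """Infer one vector per tokenised document with the trained model."""
    if ids is None:
        ids = [str(i) for i in range(len(docs))]
    if len(docs) == 0:
        return DocVectorSet(ids=[], vectors=np.empty((0, model.cfg.dim)))
    vecs = np.vstack([model.infer_vector(doc) for doc in docs])
    return DocVectorSet(ids=list(ids), vectors=vecs)


def tfidf_vectors(
    corpus: Sequence[Sequence[str]],
    ids: Sequence[str] | None = None,
    min_count: int = 1,
    smooth_idf: bool = True,
) -> DocVectorSet:
    """TF-iDF bag-of-words vectors.

    Term frequency is the raw within-document count.  The inverse document
    frequency is ``log((1+N)/(1+df)) + 1`` when ``smooth_idf`` (the
    default), or the unsmoothed ``log(N/df)`` — under which a term present
    in every document receives weight exactly 0.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if ids is None:
        ids = [str(i) for i in range(len(corpus))]
    df: dict[str, int] = {}
    tf: list[dict[str, int]] = []
    for doc in corpus:
        c: dict[str, int] = {}
        for tok in doc:
            c[tok] = c.get(tok, 0) + 1
        tf.append(c)
        for tok in c:
            df[tok] = df.get(tok, 0) + 1
    counts_all: dict[str, int] = {}
    for c in tf:
        for tok, k in c.items():
            counts_all[tok] = counts_all.get(tok, 0) + k
    vocab_words = sorted(w for w in df if counts_all[w] >= min_count)
    vocab = {w: j for j, w in enumerate(vocab_words)}
    n = len(corpus)
    if smooth_idf:
        idf = np.array(
            [math.log((1 + n) / (1 + df[w])) + 1.0 for w in vocab_words]
        )
    else:
        idf = np.array([math.log(n / df[w]) for w in vocab_words])
    X = np.zeros((n, len(vocab_words)))
    for i, c in enumerate(tf):
        for tok, k in c.items():
            j = vocab.get(tok)
            if j is not None:
                X[i, j] = k * idf[j]
    return DocVectorSet(ids=list(ids), vectors=X)


def centroid_benchmark(
    vectors: DocVectorSet,
    labels: Mapping[str, str],
    per_centroid: int,
) -> int:
    """Category-centroid retrieval score.

    For each category, the centroid is the mean vector of its members; the
    ``per_centroid`` documents nearest to the centroid by cosine similarity
    (searched over the whole set, ties broken by ascending document id) are
    retrieved, and the members of the category among them are counted.
    Returns the count summed over categories.
    """
    missing = [i for i in vectors.ids if i not in labels]
    if missing:
        raise ValueError(f"unlabelled documents: {missing[:5]}")
    cats: dict[str, list[int]] = {}
    for row, doc_id in enumerate(vectors.ids):
        cats.setdefault(labels[doc_id], []).append(row)
    for cat, rows in cats.items():
        if len(rows) < per_centroid:
            raise ValueError(
                f"category {cat!r} has {len(rows)} members < per_centroid={per_centroid}"
            )
    X = vectors.vectors
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    # rank by (-similarity, id) for deterministic ties
    id_order = np.argsort(np.argsort(vectors.ids))
    correct = 0
    for cat, rows in sorted(cats.items()):
        centroid = X[rows].mean(axis=0)
        cn = np.linalg.norm(centroid)
        sims = Xn @ (centroid / cn if cn > 0 else centroid)
        order = np.lexsort((id_order, -sims))
        nearest = order[:per_centroid]
        member = np.zeros(len(X), dtype=bool)
        member[rows] = True
        correct += int(member[nearest].sum())
    return correct
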