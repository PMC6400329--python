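# Methods

This note documents the models and procedures implemented in `mstopics`,
the parameter defaults and why they were chosen, the numerical and design
decisions made where the design was genuinely open, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Text preprocessing

Documents are tokenised by word-punct splitting with lowercasing;
punctuation-only and digit-only tokens are dropped. Surviving tokens are
stemmed with a full implementation of the classic Porter algorithm (the
five-step suffix-stripping procedure governed by the stem measure
m of `[C](VC)^m[V]`), validated against the algorithm's standard
vocabulary examples. A conservative plural/participle stripper acts as a
fallback in the (defensive) case where the primary stemmer raises or
returns an empty string; Porter by construction always returns a string,
so this path is unreachable in normal operation.

**Stop-word ordering.** Stemming precedes stop-word removal, and matching
is stemming-aware: a token is dropped if either its raw or its stemmed
form matches the raw or stemmed stop list. This prevents stemmed stop
words ("thi" from "this") from leaking into the vocabulary. The
alternative order (remove stop words on raw forms, then stem) is available
via `stop_removal="pre_stem"`. The packaged stop list is the standard
179-entry English list used throughout applied NLP.

**Summary tokens.** For human-readable cluster summaries a second stream
keeps only content words — adjectives, nouns and verbs — and replaces them
by lemmas rather than stems. POS decisions use a closed-class lexicon
(determiners, pronouns, prepositions, conjunctions, modals) plus a
morphological adverb rule (-ly, with a short exception list);
inflections of the uninformative common verbs *be*, *have* and *do* are
removed, as are any configured extra verbs. The lemmatiser is rule-based
(plural endings, -ing/-ed participles with consonant undoubling and
measure-based e-restoration, plus an irregular-form table). This is
deliberately lightweight: it serves readability of summaries, not the
clustering itself, which operates on the stemmed stream.

## Document embedding

**PV-DBOW.** Each document owns a trainable d-dimensional vector optimised
to predict the words it contains, by negative sampling against a
unigram^0.75 noise distribution, with optional subsampling of frequent
words and a linearly decaying learning rate (0.025 → 1e-4). Training is
sequential and single-threaded, hence bit-reproducible for a fixed seed.
Defaults follow the optimised full-scale configuration: d = 300,
10 epochs, window 15, min_count 5, 5 negative samples, subsampling
threshold 1e-3. (Pure PV-DBOW predicts words from the document vector
alone, so the window parameter does not enter the objective; it is
accepted for configuration compatibility.) After training, vectors for the
analysis set are obtained by *inference*: a fresh document vector is
optimised against the frozen word weights under a fixed seeding scheme, so
identical token lists always receive identical vectors. The pipeline's
`embed` stage uses this train-then-infer protocol.

For the small synthetic corpora used in tests, the model is scaled down to
d = 32, 40 epochs, min_count 2 — enough for convergence on a
100-document, ~200-word vocabulary corpus.

**TF-iDF.** Raw within-document counts times inverse document frequency.
The default iDF is the smoothed convention `log((1+N)/(1+df)) + 1`
(cross-checked against scikit-learn's implementation in the tests); the
unsmoothed `log(N/df)` — under which a ubiquitous term weighs exactly
zero — is available via `smooth_idf=False`.

**Centroid benchmark.** Embedding quality against labelled categories is
scored by retrieval: per category, the `per_centroid` documents nearest
(cosine) to the category's mean vector are retrieved from the *whole*
analysis set and its members counted. Ties are broken by ascending
document id for determinism. The score is invariant to global rescaling
of the vectors.

## Graph construction

Cosine similarities are mapped to distances D = 1 − S_cos, normalised by
the maximum *off-diagonal* entry (the diagonal is identically zero and
uninformative) to D̂ ∈ [0, 1], and flipped to Ŝ = 1 − D̂, so the most
distant pair of documents attains Ŝ = 0 exactly. If all pairwise
distances vanish the geometry is degenerate; Ŝ is then defined as all
ones with a warning rather than dividing by zero.

The MST-kNN sparsifier keeps the union of (a) the minimum spanning tree
of D̂, computed by Kruskal's algorithm with a stable
(distance, smaller index, larger index) tie-break so the edge set is
bit-reproducible under ties, and (b) each node's k nearest neighbours by
distance, self excluded, with *all* neighbours tied at the k-th distance
included and the union of directed neighbourhoods symmetrised. Kept edges
carry the Ŝ weight exactly. Default k = 13, the value at which cluster
quality saturates in the motivating analysis; the edge set is nested in k
and connected for every k ≥ 0 by the MST guarantee.

## Markov Stability

The continuous-time random walk has generator L_RW = I − D⁻¹A and kernel
P(t) = e^(−t·L_RW), computed by dense Padé matrix exponential. The
implementation is dense-only and practical to roughly N ≈ 5000 nodes;
sparsity of A does not persist in P(t), so a sparse kernel would buy
nothing at these sizes. The stationary distribution is degree-
proportional, π = d / Σd.

The quality of a partition H at time t is r(t, H) = trace Hᵀ B(t) H with
B(t) = Π P(t) − π πᵀ. Useful identities, all enforced by tests:
the entries of R(t, H) sum to 0 for every partition and t; the
single-community partition scores exactly 0; singletons at t = 0 score
1 − Σπᵢ²; and π is a left fixed point of P(t) for all t.

**Optimisation.** B(t) has negative entries by construction, so standard
modularity shortcuts that assume nonnegative weights do not apply. The
Louvain variant here works directly on the symmetrised B(t): greedy local
moves send each node to the community maximising its summed affinity
(an all-negative row detaches the node into a singleton), passes iterate
over a shuffled node order until no move improves the objective, the
partition is aggregated (B ← Hᵀ B H) and the procedure recurses. The
ensemble runs this `n_runs` times with node orders drawn from seeds
derived from a master seed by a counter; ties in the final ranking keep
the lowest run index. Defaults n_runs = 500 and n_top = 50 follow the
full-scale protocol; the test and acceptance fixtures use 20–50 runs,
which on graphs of ≤ 100 nodes reach the exhaustive-enumeration optimum
(verified for all fixture graphs with N ≤ 8 against a brute-force oracle
over all set partitions).

**Scan.** The default Markov-time grid is geometric with 200 points on
[1e-2, 1e2], matching the logarithmic resolution axis on which scales are
read; a linear grid is available for protocols specified in fixed steps.
After the per-time ensembles, a single cross-time sweep re-scores every
stored optimal partition at every time and replaces the incumbent
wherever it scores higher — one sweep, not iterated to convergence, since
the candidate set is fixed after the scan. Diagnostics: VI(t) is the mean
pairwise variation of information over the top n_top partitions at t
(the all-pairs mean being the symmetric choice), and VI(t, t′) compares
optimal partitions across times. VI is computed in nats.

**Scale selection.** A time is a candidate robust scale when its VI(t) is
a local minimum lying at or below the `dip_quantile` (default 25th
percentile) of VI(t) over the scan, and it sits inside a contiguous
plateau of at least `plateau_min_len` (default 2) grid points whose
optimal partitions differ from it by less than `plateau_eps`
(default 0.05) in VI. Automation of what is visually a dip-and-plateau
judgement requires thresholds; both are config-exposed. Trivial
partitions — a single community, or all singletons — are excluded from
candidacy: the one-community partition scores r = 0 identically and
dominates trivially as t → ∞ with an unbounded plateau, and the
all-singleton partition plays the same role as t → 0; neither carries
community information. Candidates with identical partitions (VI = 0) are
merged, keeping the longest plateau, and results are ordered by plateau
length descending.

## Evaluation

**PMI coherence.** Word probabilities are document frequencies over the
analysis set being clustered (the co-occurrence unit is the whole
document, following standard topic-coherence practice). PMI uses the
natural log; a pair that never co-occurs would be −∞, so it returns a
configurable floor, default −log N_docs — the magnitude of the smallest
observable co-occurrence probability — keeping medians defined. The
aggregate score takes, per cluster, the `top_n` (default 10) words by
*within-cluster* document frequency (ties lexicographic), computes the
median PMI over all unordered pairs, and averages over clusters weighted
by cluster size. A cluster with fewer than two distinct words contributes
the floor, with a warning.

**NMI.** I(C,D)/√(H(C)H(D)), computed from the contingency table and
cross-checked in the tests against scikit-learn's geometric-mean variant
to 1e-10. Zero-entropy partitions raise, since the score is undefined.

**Contingency z-scores.** The cluster-by-category table is standardised
against the fixed-margin (hypergeometric) null: E = n_c n_k / N and
Var = E (1 − n_c/N)(N − n_k)/(N − 1), with z = 0 where the variance
vanishes. Fixed margins are the standard null for post-hoc contingency
comparison; the z-scores are validated against scipy's hypergeometric
moments.

## Synthetic generators

**Corpus.** Documents draw `doc_length` = 40 tokens each: with
probability `keyword_rate` = 0.5 from the union of their sub-topic's 10
exclusive keywords and their theme's 8 shared keywords, otherwise from a
120-word background vocabulary. Defaults give 2 themes × 2 sub-themes ×
25 documents. The keyword balance (10 exclusive vs 8 shared) was chosen so
that *both* planted levels are expressed within the method's standard
resolution span: with a much smaller shared pool the theme level still
exists mathematically but merges only at Markov times beyond 1e2. The
theme merge sits near the upper end of the span and, for some corpus
realisations, slightly beyond it; analyses that must capture the coarse
level for arbitrary seeds extend the scan to t_max = 3e2. Vocabulary
items are pronounceable pseudo-words that pass through stemming and
stop-word removal unchanged, isolating clustering behaviour from
linguistic preprocessing.

What this generator does *not* emulate: real clinical language
(misspellings, abbreviations, negation), class imbalance, document-length
variation, polysemy, or vocabulary shared asymmetrically across themes.
Passing tests therefore demonstrate that the pipeline recovers planted
co-occurrence structure at two scales under controlled noise — not that it
will resolve any particular real corpus, where preprocessing quality and
embedding training volume matter far more.

**Graph.** `generate_multiscale_graph` plants two scales directly:
cliques (internal weight w_in = 1) paired into groups (between-clique
weight w_mid = 0.3 within a group, w_out = 0.05 across groups). If
sampling or w_out = 0 disconnects the graph, a minimal set of
epsilon-weight bridges is added with a warning so the diffusion process
remains well defined.

## Problem sizes

The test suite and the acceptance script run the method at deliberately
modest sizes — 32-node benchmark graphs, 100-document corpora, scans of
30–50 grid points with 20–50 Louvain runs per time — chosen so that the
optimiser provably attains the global optimum on the oracle-checkable
fixtures and the full suite completes in a few minutes on one CPU. The
defaults shipped in the configuration objects (d = 300, k = 13,
500 runs / top 50, 200-point grid) are the full-scale protocol.

## Known limitations

- Dense matrix exponential limits graphs to a few thousand nodes.
- The PV-DBOW implementation is sequential by design (reproducibility);
  it is not tuned for multi-million-document corpora, where a
  multi-threaded implementation would be preferred at the cost of
  bit-reproducibility.
- The POS tagger and lemmatiser are rule-based approximations adequate
  for cluster summaries, not general-purpose morphological analysis.
- Scale selection automates a visual dip-and-plateau judgement; on noisy
  scans it can report near-trivial fine scales alongside the meaningful
  ones (they rank below by plateau length), and `plateau_eps` /
  `dip_quantile` may need adjustment per dataset.
- The cross-time re-optimisation is a single sweep over the fixed
  candidate set; it does not iterate to a fixed point.
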