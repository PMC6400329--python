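"""Text normalisation for embedding and for human-readable summaries.

Two parallel token streams are produced per document:

* ``tokens`` — lowercased, punctuation/digit-free, stemmed, stop-word-free
  tokens that feed the embedding stage;
* ``summary_tokens`` — lemmatised content words (adjectives, nouns, verbs,
  minus uninformative common verbs) used for cluster word summaries, where
  aggressive stemming would hurt readability.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .stemming import stem, _measure, _ends_cvc, _ends_double_consonant

__all__ = [
    "Document",
    "load_stopwords",
    "tokenize",
    "normalize_tokens",
    "summary_tokens",
    "ngram_frequencies",
    "preprocess_documents",
    "read_corpus",
    "write_tokenised",
]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]+")
_HAS_LETTER_RE = re.compile(r"[a-z]")


@dataclass
class Document:
    """One free-text record with its derived token streams."""

    id: str
    text: str
    tokens: list[str] = field(default_factory=list)
    summary_tokens: list[str] = field(default_factory=list)
    category: str | None = None


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop list (one word per line); defaults to the packaged
    standard English list."""
    if path is None:
        text = (
            resources.files("mstopics").joinpath("data/stopwords_en.txt").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def tokenize(text: str) -> list[str]:
    """Word-punct tokenisation with lowercasing."""
    return _TOKEN_RE.findall(text.lower())


def normalize_tokens(
    text: str,
    stoplist: Iterable[str] | None = None,
    stop_removal: str = "post_stem",
) -> list[str]:
    """Normalise raw text into stemmed, stop-word-free word tokens.

    Punctuation-only and digit-only tokens are dropped.  Each surviving
    token is stemmed; stop words are removed either after stemming with
    stemming-aware matching (``stop_removal="post_stem"``, the default — a
    token is dropped if its raw or stemmed form matches the raw or stemmed
    stop list) or before stemming on the raw forms (``"pre_stem"``).
    """
    if stop_removal not in ("post_stem", "pre_stem"):
        raise ValueError(f"unknown stop_removal mode: {stop_removal!r}")
    stops = frozenset(stoplist) if stoplist is not None else load_stopwords()
    raw = [t for t in tokenize(text) if _HAS_LETTER_RE.search(t)]
    if stop_removal == "pre_stem":
        return [stem(t) for t in raw if t not in stops]
    stemmed_stops = stops | {stem(s) for s in stops}
    out = []
    for t in raw:
        st = stem(t)
        if t in stops or st in stemmed_stops:
            continue
        out.append(st)
    return out


# --- POS filtering and lemmatisation (rule/lexicon based) -------------------

# Closed-class function words: never adjective/noun/verb content.
_FUNCTION_WORDS = frozenset(
    """
    a an the this that these those some any each every either neither no
    i me my mine myself we us our ours ourselves you your yours yourself
    yourselves he him his himself she her hers herself it its itself they
    them their theirs themselves one ones who whom whose which what
    and or but nor so yet if because although though while whereas unless
    until since when whenever where wherever why how than whether as that
    of in on at by for with about against between into through during
    before after above below to from up down out off over under again
    further then once here there all both few more most other such only
    own same too very not now
    can could may might must shall should will would
    """.split()
)

# Inflections of 'be', 'have', 'do' — excluded common verbs.
_EXCLUDED_VERB_FORMS = frozenset(
    "be is am are was were been being have has had having do does did doing done".split()
)
_EXCLUDED_LEMMAS = frozenset({"be", "have", "do"})

# -ly words that are not adverbs.
_LY_ADJECTIVES = frozenset(
    "early only daily weekly monthly yearly likely unlikely elderly lonely friendly family supply reply apply multiply".split()
)

_IRREGULAR_LEMMAS = {
    # nouns
    "children": "child", "men": "man", "women": "woman", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "people": "person", "staff": "staff",
    # verbs (common past / participle forms)
    "went": "go", "gone": "go", "came": "come", "gave": "give", "given": "give",
    "taken": "take", "took": "take", "found": "find", "fell": "fall",
    "fallen": "fall", "saw": "see", "seen": "see", "said": "say", "told": "tell",
    "left": "leave", "made": "make", "got": "get", "gotten": "get",
    "sent": "send", "kept": "keep", "felt": "feel", "put": "put", "met": "meet",
    "brought": "bring", "thought": "think", "became": "become", "knew": "know",
    "known": "know", "wrote": "write", "written": "write", "broke": "break",
    "broken": "break", "gases": "gas",
}


def _undouble(stem_: str) -> str:
    # transferring -> transferr -> transfer; keep ll/ss/zz/ff (falling -> fall)
    if _ends_double_consonant(stem_) and stem_[-1] not in "lszf":
        return stem_[:-1]
    return stem_


def _restore_e(stem_: str) -> str:
    # making -> mak -> make; only for short (measure-1) CVC stems, as in the
    # Porter e-restoration rule
    if _measure(stem_) == 1 and _ends_cvc(stem_):
        return stem_ + "e"
    return stem_


def lemmatize(token: str) -> str:
    """Rule-based English lemmatiser for nouns and verbs."""
    if token in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[token]
    w = token
    # noun plurals
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith(("sses", "ches", "shes", "xes", "zes")):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")) and len(w) > 3:
        return w[:-1]
    # verb participles
    if w.endswith("ing") and len(w) > 5:
        return _restore_e(_undouble(w[:-3]))
    if w.endswith("ed") and len(w) > 4:
        return _restore_e(_undouble(w[:-2]))
    return w


def _is_content_word(token: str) -> bool:
    """Coarse POS decision: keep adjectives, nouns and verbs; drop
    closed-class function words and -ly adverbs."""
    if token in _FUNCTION_WORDS or token in _EXCLUDED_VERB_FORMS:
        return False
    if token.endswith("ly") and len(token) > 4 and token not in _LY_ADJECTIVES:
        return False
    return True


def summary_tokens(
    text: str, extra_excluded_verbs: Iterable[str] = ()
) -> list[str]:
    """Lemmatised content words (adjective/noun/verb) for summaries.

    Inflections of 'be', 'have' and 'do' (plus any configured extra common
    verbs) are removed; survivors are replaced by their lemmas.
    """
    extra = frozenset(extra_excluded_verbs)
    out = []
    for t in tokenize(text):
        if not _HAS_LETTER_RE.search(t):
            continue
        if not _is_content_word(t) or t in extra:
            continue
        lemma = lemmatize(t)
        if lemma in _EXCLUDED_LEMMAS or lemma in extra:
            continue
        out.append(lemma)
    return out


def ngram_frequencies(
    docs: Sequence[Document], n_range: tuple[int, int]
) -> dict[tuple[str, ...], int]:
    """Pooled contiguous n-gram counts over ``summary_tokens``, for
    n in ``[n_min, n_max]``, sorted by descending count (ties lexicographic)."""
    n_min, n_max = n_range
    if not (1 <= n_min <= n_max <= 3):
        raise ValueError("n_range must satisfy 1 <= n_min <= n_max <= 3")
    counts: Counter[tuple[str, ...]] = Counter()
    for doc in docs:
        toks = doc.summary_tokens
        for n in range(n_min, n_max + 1):
            for i in range(len(toks) - n + 1):
                counts[tuple(toks[i : i + n])] += 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def preprocess_documents(
    docs: Iterable[Document],
    stoplist: Iterable[str] | None = None,
    stop_removal: str = "post_stem",
    extra_excluded_verbs: Iterable[str] = (),
) -> list[Document]:
    """Populate ``tokens`` and ``summary_tokens`` on each document."""
    stops = frozenset(stoplist) if stoplist is not None else load_stopwords()
    out = []
    for doc in docs:
        doc.tokens = normalize_tokens(doc.text, stops, stop_removal)
        doc.summary_tokens = summary_tokens(doc.text, extra_excluded_verbs)
        out.append(doc)
    return out


# --- corpus I/O -------------------------------------------------------------

def read_corpus(path: str | Path) -> list[Document]:
    """Read a corpus from JSONL (objects with id/text/category) or CSV
    (columns id, text, optional category), inferred from the extension."""
    path = Path(path)
    docs: list[Document] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                docs.append(
                    Document(
                        id=str(row["id"]),
                        text=row["text"],
                        category=row.get("category") or None,
                    )
                )
    else:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                docs.append(
                    Document(
                        id=str(obj["id"]),
                        text=obj["text"],
                        category=obj.get("category"),
                    )
                )
    return docs


def write_tokenised(docs: Iterable[Document], path: str | Path) -> None:
    """Write the tokenised corpus as JSONL (id, tokens, summary_tokens)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "id": doc.id,
                        "tokens": doc.tokens,
                        "summary_tokens": doc.summary_tokens,
                        **({"category": doc.category} if doc.category else {}),
                    }
                )
                + "\n"
            )


def _iter_token_lists(docs: Iterable[Document]) -> Iterator[list[str]]:
    for doc in docs:
        yield doc.tokens
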