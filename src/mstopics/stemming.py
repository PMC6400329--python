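"""Suffix-stripping stemmers for English.

The primary stemmer is the classic Porter algorithm (1980), implemented in
full: five rule steps applied in sequence, with rule applicability governed
by the *measure* of the stem (the number of vowel-consonant alternations
``[C](VC)^m[V]``).  A conservative plural/participle stripper is provided as
a fallback for the (pathological) case where the primary stemmer raises or
returns an empty string.
"""

from __future__ import annotations

__all__ = ["porter_stem", "fallback_stem", "stem"]

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        # y is a vowel when preceded by a consonant
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC alternations in ``stem`` (Porter's m)."""
    m = 0
    i = 0
    n = len(stem)
    # skip initial consonant run
    while i < n and _is_consonant(stem, i):
        i += 1
    while True:
        while i < n and not _is_consonant(stem, i):
            i += 1
        if i >= n:
            return m
        while i < n and _is_consonant(stem, i):
            i += 1
        m += 1
        if i >= n:
            return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """*o condition: ends consonant-vowel-consonant, final not w, x or y."""
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, m_min: int | None) -> str | None:
    """If ``word`` ends in ``suffix`` and the stem measure exceeds ``m_min``,
    return the word with the suffix replaced; otherwise None (no match) or
    the word unchanged (matched but condition failed)."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if m_min is None or _measure(stem) > m_min:
        return stem + repl
    return word


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    flag = False
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        w = w[:-2]
        flag = True
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w = w[:-3]
        flag = True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_consonant(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _ends_cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("bli", "ble"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ("logi", "log"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _step5(w: str) -> str:
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]
    if _ends_double_consonant(w) and w[-1] == "l" and _measure(w[:-1]) > 1:
        w = w[:-1]
    return w


def porter_stem(word: str) -> str:
    """Stem ``word`` (assumed lowercase) with the Porter algorithm."""
    if len(word) <= 2:
        return word
    w = _step1a(word)
    w = _step1b(w)
    w = _step1c(w)
    for suffix, repl in _STEP2:
        out = _replace(w, suffix, repl, 0)
        if out is not None:
            w = out
            break
    for suffix, repl in _STEP3:
        out = _replace(w, suffix, repl, 0)
        if out is not None:
            w = out
            break
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > 1:
                # ion only strips after s or t
                if suffix != "ion" or (stem and stem[-1] in "st"):
                    w = stem
            break
    return _step5(w)


def fallback_stem(word: str) -> str:
    """Conservative plural / participle stripper used only if the primary
    stemmer fails (raises or returns an empty string)."""
    for suffix, repl in (("sses", "ss"), ("ies", "i"), ("ing", ""), ("ed", "")):
        if word.endswith(suffix) and len(word) - len(suffix) >= 3:
            return word[: len(word) - len(suffix)] + repl
    if word.endswith("s") and not word.endswith("ss") and len(word) >= 4:
        return word[:-1]
    return word


def stem(word: str) -> str:
    """Primary stem with automatic fallback on failure."""
    try:
        out = porter_stem(word)
    except Exception:  # pragma: no cover - defensive, not reachable by design
        return fallback_stem(word)
    if not out:  # pragma: no cover - defensive
        return fallback_stem(word)
    return out
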