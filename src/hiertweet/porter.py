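"""Porter affix-removal stemmer.

A faithful implementation of the classic Porter suffix-stripping algorithm
(the 1980 five-step procedure, including the author's later minor revisions
``bli -> ble`` and ``logi -> log`` that the widely distributed reference
implementation applies).  The stemmer reduces English words to root forms by
iteratively removing plural, participle and derivational suffixes, gated by
the *measure* m of the remaining stem — the number of vowel-consonant
sequences ``[C](VC)^m[V]``.

Only lowercase ASCII words are expected; words of length <= 2 are returned
unchanged, as in the reference implementation.
"""

from __future__ import annotations

__all__ = ["porter_stem"]

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    """True if word[i] is a consonant.  'y' counts as a consonant only when
    it is word-initial or follows a vowel."""
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return True if i == 0 else not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in ``stem`` (the Porter measure m)."""
    n = 0
    i = 0
    length = len(stem)
    while i < length and _is_cons(stem, i):
        i += 1
    while i < length:
        while i < length and not _is_cons(stem, i):
            i += 1
        if i >= length:
            break
        n += 1
        while i < length and _is_cons(stem, i):
            i += 1
    return n


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """consonant-vowel-consonant ending where the final consonant is not
    w, x or y — the condition *o of the algorithm."""
    if len(word) < 3:
        return False
    n = len(word)
    return (
        _is_cons(word, n - 1)
        and not _is_cons(word, n - 2)
        and _is_cons(word, n - 3)
        and word[-1] not in "wxy"
    )


def _step1ab(w: str) -> str:
    # 1a: plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]
    # 1b: past participles / gerunds
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = _step1b_cleanup(w[:-2])
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = _step1b_cleanup(w[:-3])
    return w


def _step1b_cleanup(w: str) -> str:
    if w.endswith(("at", "bl", "iz")):
        return w + "e"
    if _ends_double_cons(w) and w[-1] not in "lsz":
        return w[:-1]
    if _measure(w) == 1 and _ends_cvc(w):
        return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


# Ordered so that a nested longer suffix is tried before its tail
# (ational before tional, ization before ation); the first textual match
# decides, as in the reference implementation's per-letter switch.
_STEP2_RULES = (
    ("ational", "ate"),
    ("tional", "tion"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("izer", "ize"),
    ("bli", "ble"),
    ("alli", "al"),
    ("entli", "ent"),
    ("eli", "e"),
    ("ousli", "ous"),
    ("ization", "ize"),
    ("ation", "ate"),
    ("ator", "ate"),
    ("alism", "al"),
    ("iveness", "ive"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("aliti", "al"),
    ("iviti", "ive"),
    ("biliti", "ble"),
    ("logi", "log"),
)

_STEP3_RULES = (
    ("icate", "ic"),
    ("ative", ""),
    ("alize", "al"),
    ("iciti", "ic"),
    ("ical", "ic"),
    ("ful", ""),
    ("ness", ""),
)


def _apply_rules(w: str, rules, min_measure: int) -> str:
    for suffix, repl in rules:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > min_measure:
                return stem + repl
            return w
    return w


_STEP4_SUFFIXES_A = (
    "al", "ance", "ence", "er", "ic", "able", "ible",
    "ant", "ement", "ment", "ent",
)
_STEP4_SUFFIXES_B = ("ou", "ism", "ate", "iti", "ous", "ive", "ize")


def _step4(w: str) -> str:
    for suffix in _STEP4_SUFFIXES_A:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            return stem if _measure(stem) > 1 else w
    if w.endswith("ion"):
        stem = w[:-3]
        if stem and stem[-1] in "st":
            return stem if _measure(stem) > 1 else w
        return w
    for suffix in _STEP4_SUFFIXES_B:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            return stem if _measure(stem) > 1 else w
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        a = _measure(stem)
        if a > 1 or (a == 1 and not _ends_cvc(stem)):
            w = stem
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


def porter_stem(token: str) -> str:
    """Return the Porter stem of a lowercase word token."""
    if len(token) <= 2:
        return token
    w = _step1ab(token)
    w = _step1c(w)
    w = _apply_rules(w, _STEP2_RULES, 0)
    w = _apply_rules(w, _STEP3_RULES, 0)
    w = _step4(w)
    w = _step5(w)
    return w
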