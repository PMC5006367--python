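"""Classic Porter (1980) suffix-stripping stemmer.

Self-contained implementation of the original algorithm: five steps of
rule tables conditioned on the measure *m* of the stem (the number of
vowel–consonant sequences), with ``y`` treated as a vowel when preceded
by a consonant.  Words of length one or two are returned unchanged.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return True if i == 0 else not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences: [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (len(word) >= 2 and word[-1] == word[-2]
            and _is_consonant(word, len(word) - 1))


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x, y
    if len(word) < 3:
        return False
    return (_is_consonant(word, len(word) - 3)
            and not _is_consonant(word, len(word) - 2)
            and _is_consonant(word, len(word) - 1)
            and word[-1] not in "wxy")


def _replace(word: str, suffix: str, replacement: str, min_m: int) -> str | None:
    """Apply suffix rule if the stem's measure exceeds ``min_m`` − 1."""
    stem_part = word[: len(word) - len(suffix)]
    if _measure(stem_part) >= min_m:
        return stem_part + replacement
    return None


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        out = _replace(word, "eed", "ee", 1)
        return out if out is not None else word
    stripped = None
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        stripped = word[:-2]
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        stripped = word[:-3]
    if stripped is None:
        return word
    if stripped.endswith(("at", "bl", "iz")):
        return stripped + "e"
    if _ends_double_consonant(stripped) and stripped[-1] not in "lsz":
        return stripped[:-1]
    if _measure(stripped) == 1 and _ends_cvc(stripped):
        return stripped + "e"
    return stripped


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
    ("anci", "ance"), ("izer", "ize"), ("abli", "able"), ("alli", "al"),
    ("entli", "ent"), ("eli", "e"), ("ousli", "ous"), ("ization", "ize"),
    ("ation", "ate"), ("ator", "ate"), ("alism", "al"), ("iveness", "ive"),
    ("fulness", "ful"), ("ousness", "ous"), ("aliti", "al"),
    ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _table_step(word: str, table, min_m: int) -> str:
    for suffix, replacement in table:
        if word.endswith(suffix):
            out = _replace(word, suffix, replacement, min_m)
            return out if out is not None else word
    return word


def _step4(word: str) -> str:
    for suffix in sorted(_STEP4, key=len, reverse=True):
        if word.endswith(suffix):
            stem_part = word[: len(word) - len(suffix)]
            if _measure(stem_part) >= 2:
                if suffix == "ion" and not stem_part.endswith(("s", "t")):
                    return word
                return stem_part
            return word
    return word


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem_part = word[:-1]
        m = _measure(stem_part)
        if m > 1 or (m == 1 and not _ends_cvc(stem_part)):
            return stem_part
    return word


def _step5b(word: str) -> str:
    if (word.endswith("l") and _ends_double_consonant(word)
            and _measure(word) > 1):
        return word[:-1]
    return word


def stem(word: str) -> str:
    """Stem a lowercase alphabetic word."""
    if len(word) <= 2:
        return word
    word = _step1a(word)
    word = _step1b(word)
    word = _step1c(word)
    word = _table_step(word, _STEP2, 1)
    word = _table_step(word, _STEP3, 1)
    word = _step4(word)
    word = _step5a(word)
    word = _step5b(word)
    return word
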