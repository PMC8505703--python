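"""Neutral filler vocabulary for the synthetic generator.

Pronounceable nonsense words built from consonant-vowel syllables,
enumerated deterministically. Real-word vocabularies risk accidental
collisions with a negative lexicon; nonsense words make disjointness
checkable and (almost always) automatic. Any rare collision with a user
lexicon is simply skipped, and the result is asserted disjoint.
"""

from __future__ import annotations

from itertools import count

from .lexicon import NegativeLexicon

__all__ = ["neutral_vocabulary"]

_CONSONANTS = "bdfgjklmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]  # 75 syllables


def neutral_vocabulary(size: int, lexicon: NegativeLexicon) -> list[str]:
    """Return ``size`` distinct three-syllable words disjoint from ``lexicon``.

    Deterministic: the same (size, lexicon) always yields the same list.
    """
    if size < 1:
        raise ValueError("vocabulary size must be positive")
    n = len(_SYLLABLES)
    if size > n**3 - len(lexicon):
        raise ValueError(f"vocabulary size {size} too large")
    words: list[str] = []
    for i in count():
        w = _SYLLABLES[i % n] + _SYLLABLES[(i // n) % n] + _SYLLABLES[(i // n**2) % n]
        if w in lexicon:
            continue
        words.append(w)
        if len(words) == size:
            break
    assert not set(words) & lexicon.words
    return words
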