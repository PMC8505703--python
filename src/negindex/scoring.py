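"""Tokenization and negative-word counting.

This is the computation behind the daily negative-word total N(d): each tweet
is tokenized and every token that is a lexicon member is counted *with
multiplicity* ("fear ... fear" contributes 2).

The counter is deliberately context-blind: negation, irony and sarcasm are
not handled, so "living in a hotel is not so bad" scores 1 (the word "bad").
That behavior is part of the statistic's definition, not a bug; a regression
test pins it. Misspelled words are likewise not matched.

Tokenizer rules (one defensible realization, isolated here so alternatives
can be swapped):

* Unicode casefold.
* URLs (``http://``, ``https://``, ``www.`` prefixes) removed entirely.
* User mentions (``@name``) removed entirely.
* ``#`` stripped from hashtags; the word is kept.
* Split on any character that is not a letter, digit or apostrophe
  (underscore splits too).
* Leading/trailing apostrophes stripped; word-internal apostrophes kept, so
  "don't" stays one token.
"""

from __future__ import annotations

import re
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass, field

from .lexicon import NegativeLexicon

__all__ = ["TweetScore", "tokenize", "count_negative", "score_text"]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_MENTION_RE = re.compile(r"@\w+")
# a run of letters, digits or apostrophes (\w minus underscore, plus ')
_TOKEN_RE = re.compile(r"(?:[^\W_]|')+")


@dataclass(frozen=True)
class TweetScore:
    """Negative-word occurrences found in one tweet.

    ``negative_count`` equals the total multiplicity of ``matched_words``.
    """

    tweet_id: str
    negative_count: int
    matched_words: Counter[str] = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.negative_count != sum(self.matched_words.values()):
            raise ValueError("negative_count inconsistent with matched_words")


def tokenize(text: str) -> list[str]:
    """Split tweet text into lowercase word tokens."""
    folded = text.casefold()
    folded = _URL_RE.sub(" ", folded)
    folded = _MENTION_RE.sub(" ", folded)
    tokens = []
    for match in _TOKEN_RE.finditer(folded):
        tok = match.group().strip("'")
        if tok:
            tokens.append(tok)
    return tokens


def count_negative(
    tokens: Sequence[str], lexicon: NegativeLexicon, tweet_id: str = ""
) -> TweetScore:
    """Count lexicon-member tokens with multiplicity."""
    matched = Counter(t for t in tokens if t in lexicon)
    return TweetScore(
        tweet_id=tweet_id,
        negative_count=sum(matched.values()),
        matched_words=matched,
    )


def score_text(text: str, lexicon: NegativeLexicon, tweet_id: str = "") -> TweetScore:
    """Tokenize ``text`` and count its negative words."""
    return count_negative(tokenize(text), lexicon, tweet_id=tweet_id)
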