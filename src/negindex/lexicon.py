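"""Negative-word lexicons.

A :class:`NegativeLexicon` is a deduplicated set of lowercase single-token
words treated as unambiguously negative. Matching elsewhere in the package is
exact-token and case-insensitive: no stemming, no lemmatization, no substring
matching. Inflected forms ("worry", "worried") are therefore separate entries.

The packaged default list is a short, hand-curated vocabulary of strongly
negative English words that were frequent in COVID-era tweet streams. The
printed source list contains two duplicated entries; loading collapses them
(occurrence counting must not double-count a token because the dictionary
listed it twice) while ``raw_token_count`` preserves the printed length.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "NegativeLexicon",
    "LexiconError",
    "load_default_lexicon",
    "load_lexicon_file",
    "parse_lexicon_tokens",
    "write_lexicon_file",
]

logger = logging.getLogger(__name__)

_DEFAULT_RESOURCE = "negative_words.txt"
_DEFAULT_LABEL = "packaged default negative-word list"



class LexiconError(ValueError):
    """Raised for invalid lexicon content (empty list, multi-word entries...)."""


@dataclass(frozen=True)
class NegativeLexicon:
    """A validated, deduplicated set of lowercase negative words.

    Parameters
    ----------
    words
        Unique lowercase word strings; no whitespace, non-empty.
    source_label
        Free-text provenance of the list.
    raw_token_count
        Number of tokens in the source before deduplication
        (``raw_token_count >= len(words)``).
    """

    words: frozenset[str]
    source_label: str
    raw_token_count: int

    def __post_init__(self) -> None:
        if not self.words:
            raise LexiconError("empty lexicon")
        for w in self.words:
            if not w:
                raise LexiconError("lexicon contains an empty word")
            if w != w.casefold():
                raise LexiconError(f"lexicon word not lowercase: {w!r}")
            if any(c.isspace() for c in w):
                raise LexiconError(f"lexicon word contains whitespace: {w!r}")
        if self.raw_token_count < len(self.words):
            raise LexiconError(
                f"raw_token_count ({self.raw_token_count}) smaller than "
                f"number of unique words ({len(self.words)})"
            )

    def __contains__(self, word: object) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.words))


def parse_lexicon_tokens(
    tokens: Iterable[str], source_label: str, warn_duplicates: bool = True
) -> NegativeLexicon:
    """Build a lexicon from raw string tokens: casefold, trim, deduplicate.

    Duplicates are logged at warning level, not an error. Tokens containing
    internal whitespace are rejected: the tokenizer is single-token and a
    multi-word entry would silently never match.
    """
    dup_level = logging.WARNING if warn_duplicates else logging.DEBUG
    seen: set[str] = set()
    raw = 0
    for tok in tokens:
        word = tok.strip().casefold()
        if not word:
            continue
        raw += 1
        if any(c.isspace() for c in word):
            raise LexiconError(f"multi-word lexicon entry not supported: {tok!r}")
        if word in seen:
            logger.log(dup_level, "duplicate lexicon entry collapsed: %r", word)
        seen.add(word)
    if not seen:
        raise LexiconError("empty lexicon")
    return NegativeLexicon(
        words=frozenset(seen), source_label=source_label, raw_token_count=raw
    )


def _parse_lines(
    lines: Iterable[str], source_label: str, warn_duplicates: bool = True
) -> NegativeLexicon:
    def tokens() -> Iterator[str]:
        # entries are separated by newlines or commas only, so an entry with
        # internal whitespace ("feel bad") is caught as multi-word, not split
        for line in lines:
            body = line.split("#", 1)[0]
            yield from body.split(",")

    return parse_lexicon_tokens(tokens(), source_label, warn_duplicates)


def load_default_lexicon() -> NegativeLexicon:
    """Load the packaged default negative-word list.

    The packaged list's two duplicated entries are expected; collapsing them
    is logged at debug level only.
    """
    text = (
        resources.files("negindex.data").joinpath(_DEFAULT_RESOURCE).read_text("utf-8")
    )
    return _parse_lines(text.splitlines(), _DEFAULT_LABEL, warn_duplicates=False)


def load_lexicon_file(path: str | Path) -> NegativeLexicon:
    """Load a user lexicon from a UTF-8 text file.

    One word per line; commas also accepted as separators; ``#`` starts a
    comment. Raises :class:`FileNotFoundError` for a missing file and
    :class:`LexiconError` if no valid words remain.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        return _parse_lines(fh, source_label=str(path))


def write_lexicon_file(lexicon: NegativeLexicon, path: str | Path) -> None:
    """Write one word per line (sorted), suitable for :func:`load_lexicon_file`."""
    Path(path).write_text("\n".join(sorted(lexicon.words)) + "\n", encoding="utf-8")
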