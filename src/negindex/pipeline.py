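"""End-to-end convenience: corpus file -> daily index series."""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

from .corpus_io import (
    FilterStats,
    ReadStats,
    filter_keywords,
    filter_language,
    filter_retweets,
    read_corpus,
)
from .daily_index import IndexSeries, aggregate_daily
from .lexicon import NegativeLexicon

__all__ = ["score_corpus_file"]


def score_corpus_file(
    corpus_path: str | Path,
    lexicon: NegativeLexicon,
    language: str | None = "en",
    drop_retweets: bool = True,
    keywords: Iterable[str] | None = None,
    read_stats: ReadStats | None = None,
    language_stats: FilterStats | None = None,
) -> IndexSeries:
    """Read, filter, score and aggregate a JSONL corpus in one streaming pass.

    ``language=None`` disables the language filter; ``keywords=None``
    disables topic filtering. Filter order does not affect the result.
    """
    stream = read_corpus(corpus_path, stats=read_stats)
    if language is not None:
        stream = filter_language(stream, language, stats=language_stats)
    if drop_retweets:
        stream = filter_retweets(stream)
    if keywords is not None:
        stream = filter_keywords(stream, keywords)
    return aggregate_daily(stream, lexicon)
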