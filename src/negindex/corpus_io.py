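"""Streaming tweet-corpus I/O and stream filters.

Corpora are newline-delimited JSON (one object per line with keys ``id``,
``timestamp``, ``lang``, ``text``); ``.gz`` files are handled transparently.
Everything here is single-pass and lazy: a corpus is never held in memory,
so million-line dumps stream at constant memory.

Filters re-establish on arbitrary input the properties the analysis assumes
of its source stream: English-only (``lang == "en"``), retweet-free, and
topic-restricted (keyword filter). Malformed lines are counted, logged and
skipped rather than aborting the run — large social-media dumps always
contain junk lines — but a file that is mostly unparseable is rejected as
probably being the wrong file.

Identical texts posted by different accounts (spam) are *not* deduplicated;
users with spam-heavy corpora should clean them upstream.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import TextIO

from .scoring import tokenize

__all__ = [
    "Tweet",
    "CorpusFormatError",
    "ReadStats",
    "FilterStats",
    "read_corpus",
    "write_corpus",
    "filter_language",
    "filter_retweets",
    "filter_keywords",
]

logger = logging.getLogger(__name__)

# above this malformed-line fraction the input is probably not a corpus
_MAX_MALFORMED_FRACTION = 0.5


class CorpusFormatError(ValueError):
    """Raised when an input file is mostly unparseable as a tweet corpus."""


@dataclass(frozen=True)
class Tweet:
    """One social-media post: id, UTC timestamp, ISO-639-1 language, text."""

    id: str
    timestamp: datetime
    lang: str
    text: str


@dataclass
class ReadStats:
    """Bookkeeping filled in while :func:`read_corpus` streams a file."""

    parsed: int = 0
    skipped: int = 0


@dataclass
class FilterStats:
    kept: int = 0
    dropped: int = 0


def _parse_timestamp(raw: object) -> datetime:
    """Accept ISO-8601 strings or epoch seconds; normalize to UTC."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return datetime.fromtimestamp(float(raw), tz=timezone.utc)
    if isinstance(raw, str):
        ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
        if ts.tzinfo is None:
            return ts.replace(tzinfo=timezone.utc)
        return ts.astimezone(timezone.utc)
    raise ValueError(f"unparseable timestamp: {raw!r}")


def _parse_line(line: str) -> Tweet:
    obj = json.loads(line)
    if not isinstance(obj, dict):
        raise ValueError("line is not a JSON object")
    tid = str(obj["id"])
    if not tid:
        raise ValueError("empty tweet id")
    lang = str(obj["lang"]).strip().lower()
    return Tweet(
        id=tid,
        timestamp=_parse_timestamp(obj["timestamp"]),
        lang=lang,
        text=str(obj["text"]),
    )


def _open_text(path: Path, mode: str = "rt") -> TextIO:
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"), encoding="utf-8")  # type: ignore[arg-type]
    return open(path, mode, encoding="utf-8")


def read_corpus(path: str | Path, stats: ReadStats | None = None) -> Iterator[Tweet]:
    """Stream tweets from a JSONL corpus file in file order.

    Malformed lines are skipped with a warning and counted in ``stats``.
    Raises :class:`CorpusFormatError` at end of stream if more than half of
    the non-blank lines failed to parse, and propagates I/O errors for an
    unreadable file.
    """
    path = Path(path)
    if stats is None:
        stats = ReadStats()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                tweet = _parse_line(line)
            except (ValueError, KeyError, TypeError) as exc:
                stats.skipped += 1
                logger.warning("%s:%d: skipping malformed line (%s)", path, lineno, exc)
                continue
            stats.parsed += 1
            yield tweet
    total = stats.parsed + stats.skipped
    logger.info("%s: %d tweets read, %d malformed lines skipped", path, stats.parsed, stats.skipped)
    if total > 0 and stats.skipped / total > _MAX_MALFORMED_FRACTION:
        raise CorpusFormatError(
            f"{path}: {stats.skipped}/{total} lines malformed; "
            "this does not look like a tweet corpus"
        )


def write_corpus(tweets: Iterable[Tweet], path: str | Path) -> int:
    """Write tweets as JSONL (gzip if the path ends in .gz); returns count."""
    path = Path(path)
    n = 0
    with _open_text(path, "wt") as fh:
        for t in tweets:
            fh.write(
                json.dumps(
                    {
                        "id": t.id,
                        "timestamp": t.timestamp.astimezone(timezone.utc).isoformat(),
                        "lang": t.lang,
                        "text": t.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


def filter_language(
    stream: Iterable[Tweet], lang: str = "en", stats: FilterStats | None = None
) -> Iterator[Tweet]:
    """Keep only tweets whose language code equals ``lang``."""
    stats = stats if stats is not None else FilterStats()
    for t in stream:
        if t.lang == lang:
            stats.kept += 1
            yield t
        else:
            stats.dropped += 1
    logger.info("language filter (%s): kept %d, dropped %d", lang, stats.kept, stats.dropped)


def filter_retweets(
    stream: Iterable[Tweet], stats: FilterStats | None = None
) -> Iterator[Tweet]:
    """Drop re-posts: tweets whose text starts with the literal prefix ``RT @``."""
    stats = stats if stats is not None else FilterStats()
    for t in stream:
        if t.text.lstrip().startswith("RT @"):
            stats.dropped += 1
        else:
            stats.kept += 1
            yield t
    logger.info("retweet filter: kept %d, dropped %d", stats.kept, stats.dropped)


def filter_keywords(
    stream: Iterable[Tweet],
    keywords: Iterable[str],
    stats: FilterStats | None = None,
) -> Iterator[Tweet]:
    """Keep tweets whose tokenized text contains at least one keyword.

    Uses the same tokenizer as scoring, so "COVID!" matches keyword "covid".
    """
    keyset = {k.strip().casefold() for k in keywords if k.strip()}
    if not keyset:
        raise ValueError("keyword filter requires a non-empty keyword list")
    stats = stats if stats is not None else FilterStats()
    for t in stream:
        if keyset.intersection(tokenize(t.text)):
            stats.kept += 1
            yield t
        else:
            stats.dropped += 1
    logger.info("keyword filter: kept %d, dropped %d", stats.kept, stats.dropped)
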