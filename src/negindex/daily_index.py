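"""Daily aggregation and the negative frequency index.

For each UTC calendar day d the pipeline records T(d), the number of tweets,
and N(d), the total occurrences of negative-lexicon words across those
tweets. The negative frequency index is their ratio::

    I(d) = N(d) / T(d)

which normalizes away platform-volume drift so days with very different
tweet counts are comparable. The two integer counts are the source of truth;
I(d) is always re-derivable from them. A day with T(d) = 0 has an *undefined*
index (NaN), which is represented and flagged — never imputed and never
silently turned into a zero.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import Tweet
from .lexicon import NegativeLexicon
from .scoring import score_text

__all__ = [
    "DailySummary",
    "IndexSeries",
    "negative_frequency_index",
    "aggregate_daily",
    "write_series",
    "read_series",
]

logger = logging.getLogger(__name__)

# tolerance for accepting a stored index against N/T on read
_INDEX_CONSISTENCY_TOL = 1e-12


def negative_frequency_index(negative_words: int, total_tweets: int) -> float:
    """Return N/T, or NaN (the missing marker) when T is zero.

    Negative inputs are a caller error and raise ``ValueError``.
    """
    if negative_words < 0 or total_tweets < 0:
        raise ValueError("counts must be non-negative")
    if total_tweets == 0:
        return math.nan
    return negative_words / total_tweets


@dataclass(frozen=True)
class DailySummary:
    """Per-day triple (T(d), N(d), I(d)); the core daily statistic."""

    day: date
    total_tweets: int
    negative_words: int

    def __post_init__(self) -> None:
        if self.total_tweets < 0 or self.negative_words < 0:
            raise ValueError("counts must be non-negative")

    @property
    def index(self) -> float:
        """I(d) = N(d)/T(d); NaN when the day has no tweets."""
        return negative_frequency_index(self.negative_words, self.total_tweets)

    @property
    def missing(self) -> bool:
        return self.total_tweets == 0


class IndexSeries:
    """A contiguous daily series of (T(d), N(d), I(d)).

    Dates are strictly increasing with no gaps: interior days with no tweets
    are present with T = N = 0 and a NaN index (flagged missing). Backed by a
    pandas DataFrame with a daily ``DatetimeIndex`` and integer columns
    ``total_tweets`` and ``negative_words`` plus the float ``index`` column.
    """

    def __init__(self, frame: pd.DataFrame):
        if not frame.empty:
            if not isinstance(frame.index, pd.DatetimeIndex):
                raise TypeError("IndexSeries requires a DatetimeIndex")
            expected = pd.date_range(frame.index[0], frame.index[-1], freq="D")
            if not frame.index.equals(expected):
                raise ValueError("IndexSeries dates must be contiguous daily and increasing")
            if (frame["total_tweets"] < 0).any() or (frame["negative_words"] < 0).any():
                raise ValueError("counts must be non-negative")
        self._frame = frame

    # ------------------------------------------------------------------ build
    @classmethod
    def from_counts(
        cls,
        days: Iterable[date],
        total_tweets: Iterable[int],
        negative_words: Iterable[int],
    ) -> "IndexSeries":
        """Build a series from parallel day/count sequences (gaps filled)."""
        days = list(days)
        frame = pd.DataFrame(
            {
                "total_tweets": np.asarray(list(total_tweets), dtype=np.int64),
                "negative_words": np.asarray(list(negative_words), dtype=np.int64),
            },
            index=pd.DatetimeIndex(pd.to_datetime(days)),
        )
        if frame.index.has_duplicates:
            raise ValueError("duplicate days")
        frame = frame.sort_index()
        if len(frame):
            full = pd.date_range(frame.index[0], frame.index[-1], freq="D")
            frame = frame.reindex(full, fill_value=0)
        frame["index"] = np.where(
            frame["total_tweets"] > 0,
            frame["negative_words"] / frame["total_tweets"].replace(0, 1),
            np.nan,
        )
        return cls(frame)

    @classmethod
    def empty(cls) -> "IndexSeries":
        frame = pd.DataFrame(
            {
                "total_tweets": pd.Series(dtype=np.int64),
                "negative_words": pd.Series(dtype=np.int64),
                "index": pd.Series(dtype=float),
            },
            index=pd.DatetimeIndex([]),
        )
        return cls(frame)

    # ------------------------------------------------------------------ views
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (copy-free; treat as read-only)."""
        return self._frame

    @property
    def index_values(self) -> pd.Series:
        """I(d) as a float Series (NaN on missing days)."""
        return self._frame["index"]

    @property
    def days(self) -> list[date]:
        return [ts.date() for ts in self._frame.index]

    @property
    def date_range(self) -> tuple[date, date] | None:
        if self._frame.empty:
            return None
        return self._frame.index[0].date(), self._frame.index[-1].date()

    @property
    def total_tweet_count(self) -> int:
        return int(self._frame["total_tweets"].sum())

    @property
    def total_negative_words(self) -> int:
        return int(self._frame["negative_words"].sum())

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[DailySummary]:
        for ts, row in self._frame.iterrows():
            yield DailySummary(
                day=ts.date(),
                total_tweets=int(row["total_tweets"]),
                negative_words=int(row["negative_words"]),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndexSeries):
            return NotImplemented
        return self._frame[["total_tweets", "negative_words"]].equals(
            other._frame[["total_tweets", "negative_words"]]
        ) and self._frame.index.equals(other._frame.index)

    def subset(self, start: date, end: date) -> "IndexSeries":
        """Rows with start <= day <= end (still contiguous)."""
        sub = self._frame.loc[pd.Timestamp(start) : pd.Timestamp(end)]
        return IndexSeries(sub)


def aggregate_daily(stream: Iterable[Tweet], lexicon: NegativeLexicon) -> IndexSeries:
    """One streaming pass: per UTC day, count tweets and negative words.

    An empty stream yields an empty series with a warning.
    """
    totals: dict[date, int] = defaultdict(int)
    negatives: dict[date, int] = defaultdict(int)
    for tweet in stream:
        day = tweet.timestamp.date()
        totals[day] += 1
        negatives[day] += score_text(tweet.text, lexicon, tweet_id=tweet.id).negative_count
    if not totals:
        logger.warning("aggregate_daily: empty stream, returning empty series")
        return IndexSeries.empty()
    days = sorted(totals)
    return IndexSeries.from_counts(
        days, [totals[d] for d in days], [negatives[d] for d in days]
    )


def write_series(series: IndexSeries, path: str | Path) -> None:
    """Write CSV with header ``day,total_tweets,negative_words,index``.

    ISO dates; missing days (T = 0) get an empty index field. Integers
    round-trip losslessly and the index is re-derivable from the counts.
    """
    out = series.frame.copy()
    out.insert(0, "day", [d.isoformat() for d in series.days])
    out.to_csv(path, index=False, float_format="%.17g")


def read_series(path: str | Path) -> IndexSeries:
    """Read a series CSV written by :func:`write_series`.

    A row whose stored index disagrees with N/T beyond 1e-12 triggers a
    validation warning (the counts win).
    """
    frame = pd.read_csv(path, dtype={"total_tweets": np.int64, "negative_words": np.int64})
    series = IndexSeries.from_counts(
        [date.fromisoformat(str(d)) for d in frame["day"]],
        frame["total_tweets"],
        frame["negative_words"],
    )
    if "index" in frame.columns:
        stored = pd.to_numeric(frame["index"], errors="coerce")
        derived = series.index_values.to_numpy()
        both = ~np.isnan(stored.to_numpy()) & ~np.isnan(derived)
        bad = np.abs(stored.to_numpy()[both] - derived[both]) > _INDEX_CONSISTENCY_TOL
        if bad.any():
            logger.warning(
                "%s: %d rows have a stored index inconsistent with N/T; "
                "re-derived from the counts",
                path,
                int(bad.sum()),
            )
    return series
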