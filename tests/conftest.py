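import json
from datetime import date, datetime, timezone

import pytest

from negindex import IndexSeries, Tweet, load_default_lexicon


@pytest.fixture(scope="session")
def default_lexicon():
    return load_default_lexicon()


@pytest.fixture
def make_tweet():
    def _make(text, day="2020-03-01", lang="en", tid=None, second=0):
        ts = datetime.fromisoformat(day).replace(tzinfo=timezone.utc)
        ts = ts.replace(hour=second // 3600, minute=(second // 60) % 60, second=second % 60)
        return Tweet(id=tid or f"{day}-{second}", timestamp=ts, lang=lang, text=text)

    return _make


@pytest.fixture
def write_jsonl(tmp_path):
    """Write raw dict records (or pre-formed strings) as a JSONL file."""

    def _write(records, name="corpus.jsonl"):
        path = tmp_path / name
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(rec if isinstance(rec, str) else json.dumps(rec))
                fh.write("\n")
        return path

    return _write


@pytest.fixture
def series_from_counts():
    def _make(counts, start="2020-03-01"):
        """counts: list of (T, N) starting at `start`, one per day."""
        d0 = date.fromisoformat(start)
        days = [date.fromordinal(d0.toordinal() + i) for i in range(len(counts))]
        return IndexSeries.from_counts(
            days, [t for t, _ in counts], [n for _, n in counts]
        )

    return _make
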