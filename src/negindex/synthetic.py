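"""Seeded synthetic tweet corpora with known daily negativity.

The generator emulates the statistical structure the analysis assumes of a
real COVID-era tweet stream, so every pipeline stage can be exercised and
validated without platform access:

* per-day tweet volumes are Poisson around a mean volume;
* each tweet carries a Poisson number of negative-lexicon tokens (drawn
  uniformly from the lexicon) mixed into neutral filler tokens, so the
  expected index E[I(d)] equals the per-tweet intensity λ(d) exactly;
* λ(d) follows a plateau-then-linear-decline profile, optionally scaled up
  over short event windows (news spikes);
* a configurable fraction of tweets is tagged with a non-English language
  code, which the pipeline's language filter must remove.

The neutral vocabulary is made of pronounceable nonsense words constructed
to be disjoint from the lexicon (asserted), so ground-truth bookkeeping is
exact: the generator records the *realized* per-day totals T(d) and negative
counts N(d), and :func:`ground_truth_check` verifies the real pipeline
reproduces them to the tweet.

All randomness flows from one integer seed; per-day substreams are derived
deterministically from (seed, day ordinal), so output files are
byte-identical across runs with the same profile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import ReadStats, filter_language, read_corpus
from .daily_index import IndexSeries, aggregate_daily
from .lexicon import NegativeLexicon
from .synthetic_vocab import neutral_vocabulary

__all__ = [
    "Spike",
    "SyntheticProfile",
    "GenerationResult",
    "GroundTruthReport",
    "generate_corpus",
    "simulate_daily_counts",
    "read_ground_truth",
    "ground_truth_check",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Spike:
    """A short event window multiplying λ(d) by ``factor``."""

    start: date
    end: date
    factor: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("spike end before start")
        if self.factor < 0:
            raise ValueError("spike factor must be non-negative")


@dataclass(frozen=True)
class SyntheticProfile:
    """Generator parameters for one synthetic corpus.

    Defaults mirror the study conditions the pipeline is meant to recover: a
    plateau of λ = 0.165 negative occurrences per tweet (the middle of the
    observed [0.15, 0.18] plateau band), then a linear decline of
    −5×10⁻⁴ per day, at 5,000 tweets per day.
    """

    start: date
    end: date
    tweets_per_day: float = 5000.0
    plateau_lambda: float = 0.165
    decline_start: date | None = None
    decline_slope: float = -5e-4  # λ change per day after decline_start
    spikes: tuple[Spike, ...] = ()
    tweet_length: float = 12.0  # mean tokens per tweet
    neutral_vocab_size: int = 2000
    lang_mix: float = 0.0  # fraction of non-"en" tweets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("profile end before start")
        if self.tweets_per_day < 0:
            raise ValueError("tweets_per_day must be non-negative")
        if not 0 <= self.lang_mix <= 1:
            raise ValueError("lang_mix must be in [0, 1]")
        if self.plateau_lambda < 0:
            raise ValueError("plateau_lambda must be non-negative")
        if self.neutral_vocab_size < 1:
            raise ValueError("neutral_vocab_size must be positive")
        for d in self.days():
            lam = self.lambda_on(d)
            if lam < 0:
                raise ValueError(
                    f"lambda profile goes negative on {d} (λ={lam:.3g}); "
                    "shorten the decline or flatten the slope"
                )

    def days(self) -> list[date]:
        n = (self.end - self.start).days + 1
        return [self.start + timedelta(days=i) for i in range(n)]

    def lambda_on(self, day: date) -> float:
        """Expected negative-word occurrences per tweet on ``day``."""
        lam = self.plateau_lambda
        if self.decline_start is not None and day >= self.decline_start:
            lam += self.decline_slope * (day - self.decline_start).days
        for spike in self.spikes:
            if spike.start <= day <= spike.end:
                lam *= spike.factor
        return lam


@dataclass(frozen=True)
class GenerationResult:
    corpus_path: Path
    truth_path: Path
    n_days: int
    tweets_written: int
    tweets_english: int
    mean_lambda: float


def _day_rng(seed: int, day: date) -> np.random.Generator:
    # deterministic per-day substream; ordinals are < 2**31
    return np.random.default_rng([seed, day.toordinal()])


def generate_corpus(
    profile: SyntheticProfile,
    lexicon: NegativeLexicon,
    corpus_path: str | Path,
    truth_path: str | Path,
) -> GenerationResult:
    """Write a JSONL corpus plus a ground-truth CSV of realized daily counts.

    The truth file has columns ``day,lambda,realized_T,realized_N`` where the
    realized counts cover the tweets the pipeline should keep (English ones);
    they are exact bookkeeping, not expectations.
    """
    corpus_path = Path(corpus_path)
    truth_path = Path(truth_path)
    lex_words = sorted(lexicon.words)
    vocab = neutral_vocabulary(profile.neutral_vocab_size, lexicon)
    assert not set(vocab) & lexicon.words, "neutral vocabulary collides with lexicon"

    rows = []
    tweets_written = 0
    tweets_english = 0
    with corpus_path.open("w", encoding="utf-8") as fh:
        for day in profile.days():
            rng = _day_rng(profile.seed, day)
            lam = profile.lambda_on(day)
            volume = int(rng.poisson(profile.tweets_per_day))
            seconds = np.sort(rng.integers(0, 86400, size=volume))
            is_en = rng.random(volume) >= profile.lang_mix
            n_neg = rng.poisson(lam, size=volume)
            n_neutral = np.maximum(rng.poisson(profile.tweet_length, size=volume) - n_neg, 0)
            # draw the whole day's tokens in two vectorized calls
            neg_pool = [lex_words[j] for j in rng.integers(0, len(lex_words), int(n_neg.sum()))]
            neu_pool = [vocab[j] for j in rng.integers(0, len(vocab), int(n_neutral.sum()))]
            p_neg = p_neu = 0
            realized_t = 0
            realized_n = 0
            midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
            for i in range(volume):
                k = int(n_neg[i])
                m = int(n_neutral[i])
                tokens = neg_pool[p_neg : p_neg + k] + neu_pool[p_neu : p_neu + m]
                p_neg += k
                p_neu += m
                if k and m:  # mix negative tokens into the filler
                    order = rng.permutation(k + m)
                    tokens = [tokens[j] for j in order]
                text = " ".join(tokens)
                lang = "en" if is_en[i] else "es"
                ts = midnight + timedelta(seconds=int(seconds[i]))
                record = {
                    "id": f"{day.isoformat()}-{i:06d}",
                    "timestamp": ts.isoformat(),
                    "lang": lang,
                    "text": text,
                }
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")
                tweets_written += 1
                if is_en[i]:
                    tweets_english += 1
                    realized_t += 1
                    realized_n += k
            rows.append((day.isoformat(), lam, realized_t, realized_n))

    truth = pd.DataFrame(rows, columns=["day", "lambda", "realized_T", "realized_N"])
    truth.to_csv(truth_path, index=False, float_format="%.17g")
    mean_lambda = float(np.mean([profile.lambda_on(d) for d in profile.days()]))
    logger.info(
        "synthetic corpus: %d days, %d tweets (%d en) -> %s",
        len(rows),
        tweets_written,
        tweets_english,
        corpus_path,
    )
    return GenerationResult(
        corpus_path=corpus_path,
        truth_path=truth_path,
        n_days=len(rows),
        tweets_written=tweets_written,
        tweets_english=tweets_english,
        mean_lambda=mean_lambda,
    )


def simulate_daily_counts(profile: SyntheticProfile) -> IndexSeries:
    """Draw daily (T(d), N(d)) directly, without writing tweet text.

    Distributionally identical to scoring a generated corpus after the
    English filter: the English volume is a Poisson thinning of the daily
    volume, and the day's negative total — a sum of per-tweet Poisson
    counts — is Poisson with mean T(d)·λ(d). Useful for replicate-heavy
    statistical checks where writing and re-reading text adds nothing.
    """
    days = profile.days()
    totals = np.empty(len(days), dtype=np.int64)
    negs = np.empty(len(days), dtype=np.int64)
    en_rate = profile.tweets_per_day * (1.0 - profile.lang_mix)
    for j, day in enumerate(days):
        rng = _day_rng(profile.seed, day)
        t = int(rng.poisson(en_rate))
        totals[j] = t
        negs[j] = int(rng.poisson(t * profile.lambda_on(day)))
    return IndexSeries.from_counts(days, totals, negs)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    """Load a ground-truth CSV (day, lambda, realized_T, realized_N)."""
    frame = pd.read_csv(
        path, dtype={"realized_T": np.int64, "realized_N": np.int64}
    )
    frame["day"] = [date.fromisoformat(str(d)) for d in frame["day"]]
    return frame


@dataclass(frozen=True)
class GroundTruthReport:
    ok: bool
    n_days: int
    mismatches: tuple[str, ...] = field(default_factory=tuple)

    def __str__(self) -> str:
        if self.ok:
            return f"ground truth verified on {self.n_days} days"
        return "ground truth MISMATCH:\n" + "\n".join(self.mismatches)


def ground_truth_check(
    corpus_path: str | Path, truth_path: str | Path, lexicon: NegativeLexicon
) -> GroundTruthReport:
    """Re-score a generated corpus and compare daily counts with the truth file.

    Runs the real pipeline — read, English filter, tokenize, count,
    aggregate — and demands *exact* equality of T(d) and N(d) with the
    generator's bookkeeping on every day.
    """
    truth = read_ground_truth(truth_path)
    stats = ReadStats()
    stream = filter_language(read_corpus(corpus_path, stats=stats), "en")
    series = aggregate_daily(stream, lexicon)
    by_day = {s.day: s for s in series}
    mismatches: list[str] = []
    for row in truth.itertuples(index=False):
        got = by_day.get(row.day)
        got_t = got.total_tweets if got else 0
        got_n = got.negative_words if got else 0
        if got_t != row.realized_T:
            mismatches.append(
                f"{row.day}: T pipeline={got_t} truth={row.realized_T}"
            )
        if got_n != row.realized_N:
            mismatches.append(
                f"{row.day}: N pipeline={got_n} truth={row.realized_N}"
            )
    extra = set(by_day) - set(truth["day"])
    for day in sorted(extra):
        s = by_day[day]
        if s.total_tweets or s.negative_words:
            mismatches.append(f"{day}: day absent from truth file")
    return GroundTruthReport(
        ok=not mismatches, n_days=len(truth), mismatches=tuple(mismatches)
    )
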