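# negindex

Lexicon-based measurement of negative perception in a tweet stream.

During the COVID-19 pandemic, researchers tracked the public's mood by
counting how often a fixed list of strongly negative English words ("panic",
"fear", "anxiety", ...) appeared in COVID-related Twitter posts. `negindex`
implements that measurement as a tested, reproducible pipeline for anyone
who has (or can simulate) a corpus of timestamped posts:

* a packaged **negative-word lexicon** (108 unique lowercase words) plus
  support for user-supplied word lists;
* a streaming **JSONL corpus reader** with the stream filters the analysis
  assumes (English-only, retweet-free, topic keywords);
* a context-blind **token counter** — exact-token, case-insensitive matching
  with multiplicity, no stemming, no negation handling;
* daily aggregation into the **negative frequency index**

  $$I(d) = \frac{N(d)}{T(d)}$$

  where, for calendar day $d$ (UTC), $N(d)$ is the total count of lexicon
  words across all posts and $T(d)$ is the number of posts — the
  normalization makes days with different platform volumes comparable;
* **trend characterization**: centered rolling mean, windowed OLS with a
  95% confidence interval on the slope, plateau band checks, permutation
  tests for window contrasts, and Pearson correlation against external
  daily series (deaths per day, vaccination share);
* a seeded **synthetic corpus generator** with exact per-day ground truth,
  so the whole pipeline is testable end-to-end without platform access.

The statistic is deliberately simple and deliberately literal: the phrase
*"living in a hotel is not so bad"* counts one negative occurrence ("bad").
That context-blindness is part of the measure's definition and is pinned by
a regression test, not "fixed".

## Worked example

```python
from negindex import load_default_lexicon, score_text
lexicon = load_default_lexicon()
score = score_text("living in a hotel is not so bad", lexicon)
print(score.negative_count, dict(score.matched_words))
# 1 {'bad': 1}
```

End to end, on a simulated corpus with a known 60-day plateau at
$\lambda = 0.165$ negative words per tweet followed by a 120-day linear
decline of $-5\times10^{-4}$ per day at 5,000 tweets/day
(`examples/03_trend_decline.py`):

```
plateau: I(d) in [0.1492, 0.1835], 97% of 60 days inside [0.15, 0.18]
decline: slope -4.88e-04/day (95% CI [-5.14e-04, -4.63e-04]), R² = 0.925
true slope -5.00e-04/day is inside the CI
window means 0.1641 vs 0.1347: difference +0.0294, permutation p = 1.00e-04
```

The plateau stays in the expected [0.15, 0.18] band, the OLS fit recovers
the programmed decline within its confidence interval, and the permutation
test puts the plateau/decline contrast at the smallest p the 10,000
permutations can resolve. The other scripts in `examples/` walk through
scoring, simulation + ground-truth verification, and external-series
correlation, each printing and explaining its numbers.

## Command line

A thin CLI wraps the library for shell use:

```bash
negindex simulate --start 2020-09-01 --end 2021-02-28 --seed 7 \
    --decline-start 2020-12-01 --out corpus.jsonl --truth truth.csv
negindex score --corpus corpus.jsonl --out series.csv
negindex trend --series series.csv --report report.json --plot-dir plots \
    --fit-window 2020-12-01:2021-02-28 --band 0.15,0.18
```

`score` accepts any JSONL corpus with `id`, `timestamp`, `lang`, `text`
fields (gzip transparently); `trend` emits a machine-readable JSON report
and PNG panels (daily counts, index with fitted line, index vs external
series). Defaults can live in a TOML config (`--config`), with flags
overriding.

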