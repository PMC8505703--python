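# Methods

## The statistic

For each UTC calendar day `d`, the pipeline records two integers over the
post-filter tweet stream: `T(d)`, the number of tweets, and `N(d)`, the
total number of occurrences of negative-lexicon words across those tweets
(with multiplicity — a tweet containing "fear ... fear" contributes 2).
The negative frequency index is

    I(d) = N(d) / T(d),

the average number of negative words per tweet that day. Normalizing by
volume matters because platform activity drifts over months; the raw count
series `N(d)` and the index series move together but only the latter is
comparable across days. The integers are the source of truth: `I(d)` is
stored as a float but always re-derivable, and the CSV reader warns if a
stored index disagrees with `N/T` beyond 1e-12 (the counts win). A day with
`T(d) = 0` has an undefined index, represented as NaN and flagged missing;
missing days are excluded from every downstream computation, never imputed
— no defensible imputation rule exists for an undefined ratio.

`T(d)` is defined post-filter (after the English filter and any retweet or
keyword filtering), so numerator and denominator describe the same
population of posts.

## Lexicon and matching

The default lexicon is a short, hand-curated list of strongly negative
English words: 110 printed tokens collapsing to 108 unique entries (two
entries appear twice in the printed source; treating the duplicates as
typos and collapsing them is required for correctness — a counting
dictionary must not list a token twice). Matching is exact-token and
case-insensitive with no stemming: "worry" and "worried" are separate
entries, "mad" does not match inside "made", and misspellings do not match
at all. Multi-word entries in user lexicons are rejected with an error
rather than silently never matching, because the tokenizer is single-token.

The tokenizer (one defensible realization, isolated in `scoring.py` so
alternatives can be swapped): Unicode casefold; URLs (`http://`,
`https://`, `www.`) and `@mentions` removed entirely; `#` stripped from
hashtags keeping the word; split on any character that is not a letter,
digit or apostrophe (underscore splits); edge apostrophes trimmed so
"don't" survives as one token but "'tis" becomes "tis". The test suite
pins the tokenizer to an independently written character-scanner oracle on
1,000 seeded synthetic tweets, exactly.

Counting is context-blind by construction: negation, irony and sarcasm are
invisible to it ("not so bad" scores 1). This is the definition of the
statistic, pinned as a regression test; "correcting" it would change what
is being measured.

## Trend characterization

All trend operations drop missing days.

* **Rolling mean** — centered moving average, default 7 days (the weekly
  posting cycle); endpoints use shrunken windows; the window must be odd so
  "centered" is well defined.
* **Linear trend** — ordinary least squares of `I(d)` on integer day offset
  from the window start, written out as the closed-form normal equations.
  The x-parameterization makes the intercept the fitted index at the
  window's first day. The 95% CI on the slope uses the residual standard
  error and a Student-t critical value with n−2 degrees of freedom. The
  implementation is cross-checked against statsmodels OLS to 1e-10 on 100
  random series. For a constant series (zero total variation) R² is
  defined as 1.0, since the residuals are exactly zero.
* **Range check** — extrema plus the fraction of non-missing days inside a
  stated band; used for plateau claims such as "the index stays within
  [0.15, 0.18]".
* **Window contrast** — difference of window means with a seeded two-sided
  permutation test (default 10,000 label permutations, +1-corrected so p is
  never exactly 0, with a 1e-15 tolerance on the ≥ comparison to make ties
  deterministic). A permutation test is used because no parametric model of
  the day-to-day noise is assumed; its p-value is verified uniform under an
  exchangeable null (KS check over 500 seeded replicates) and against
  exhaustive enumeration at small n.
* **External correlation** — Pearson r on date-intersected pairs after
  shifting the external series forward by `lag_days` (positive lag means
  the external series leads). External series arrive as 2-column
  `date,value` CSVs. Sparse cumulative series (weekly vaccination share)
  may be forward-filled at most 6 days; incidence series (daily deaths)
  should not be filled, and filling is therefore opt-in. Correlation is
  reported as association only.

## Synthetic corpus generator

The generator emulates exactly the features the analysis relies on, with
everything else stripped away:

* daily volume ~ Poisson(`tweets_per_day`), default 5,000;
* per-tweet negative-token count ~ Poisson(λ(d)); Poisson rather than
  Bernoulli because the counter's semantics are occurrences with
  multiplicity, and it makes E[I(d)] = λ(d) exactly, so recovery tests are
  clean;
* λ(d) is piecewise: a plateau (default 0.165, the center of the
  [0.15, 0.18] band) until `decline_start`, then linear in days with slope
  `decline_slope` (default −5×10⁻⁴/day), multiplied by any active spike
  factors (short event windows of elevated negativity); profiles that would
  drive λ below zero are rejected at construction;
* negative tokens are drawn uniformly from the lexicon; filler tokens come
  from a deterministic vocabulary of pronounceable three-syllable nonsense
  words, constructed disjoint from the lexicon and asserted so — real-word
  fillers would risk accidental matches and break exact bookkeeping;
* a `lang_mix` fraction of tweets is tagged non-English to exercise the
  language filter; ground truth records only the English tweets the
  pipeline should keep;
* one integer seed drives everything; per-day substreams are seeded by
  (seed, day ordinal), so corpus and truth files are byte-identical across
  runs.

The ground-truth CSV stores the *realized* daily `T(d)` and `N(d)` (not
expectations), and `ground_truth_check` re-scores the corpus through the
real pipeline demanding exact equality on every day — any tokenizer leakage
between filler and lexicon words would surface here.

What the generator does **not** emulate: real linguistic structure,
hashtag/URL frequencies, bot or anti-vaccine subpopulations, spam
duplication, geographic mixture, or drift in platform volume. Passing
tests therefore demonstrate that the pipeline measures what it is defined
to measure, not that the lexicon captures human sentiment.

`simulate_daily_counts` draws the daily pair (T, N) directly —
English volume as a Poisson thinning, the day's negative total as
Poisson(T·λ) by superposition — which is distributionally identical to
generating and re-scoring text. Replicate-heavy statistical checks (e.g.
slope-CI coverage over 20 seeded replicates) use it because writing and
re-reading ~18 M tweets of text would add cost but no information; the
exactness of the text path itself is established separately by the
ground-truth check.

## Problem sizes and numerical choices

The acceptance run generates one full text corpus of 180 days at 5,000
tweets/day (~0.9 M tweets, under a minute end to end) and 20 count-level
replicates for CI coverage. The test suite uses smaller corpora (hundreds
of tweets/day) everywhere except the single plateau-band check, which
scores a 60-day, 5,000 tweets/day text corpus.

Noteworthy edge handling: timestamps accepted as ISO-8601 (naive assumed
UTC) or epoch seconds, normalized to UTC; day boundaries are UTC because
the source streams are global and no timezone is otherwise defensible;
malformed corpus lines are counted, logged and skipped, but a file whose
non-blank lines are >50% malformed is rejected as probably not a corpus;
identical texts are not deduplicated (documented for users with
spam-heavy corpora).

## Limitations

The lexicon is small and fixed; the counter ignores context, negation and
misspellings; English only; daily resolution only; correlation with
external series is association, not causal inference; and synthetic
validation bounds software correctness, not construct validity of
word-counting as a sentiment measure.
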