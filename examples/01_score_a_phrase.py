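"""Score a single phrase with the default negative-word lexicon.

The counter is deliberately context-blind: it counts lexicon words with
multiplicity and ignores negation, so "not so bad" still registers "bad".
"""

from negindex import load_default_lexicon, score_text, tokenize

lexicon = load_default_lexicon()
print(f"lexicon: {len(lexicon)} unique words "
      f"({lexicon.raw_token_count} before deduplication)")

phrase = "living in a hotel is not so bad"
print(f"\nphrase : {phrase!r}")
print(f"tokens : {tokenize(phrase)}")

score = score_text(phrase, lexicon)
print(f"negative occurrences: {score.negative_count} -> {dict(score.matched_words)}")
# 1 occurrence ("bad"): the phrase reads positive to a human, but the
# statistic is defined as a raw negative-word count, and that is the point.
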