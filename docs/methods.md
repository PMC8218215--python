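# Methods

This note records the model behind each pipeline stage, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Filtering cascade

The unit of observation is a single post. The cascade runs in a fixed
order — keyword → retweets → language → exclusion phrases → deleted-account
drop → bot/nonbot partition — and every stage appends `(stage, removed)` to
a ledger whose conservation identity
`input_count = output_count + Σ removed` is checked after every run.
Retweet and language filtering commute on the final kept set (only the
ledger lines differ), which the suite asserts as a property.

Decisions taken where the procedure admits alternatives:

- **Keyword matching** operates on *raw* text, case-insensitively, as plain
  substring containment. This makes `#nicotine` match automatically, and it
  must run before normalization because the default hashtag handling would
  delete the hashtag token entirely.
- **Retweet detection** accepts either signal found in streamed records:
  the `is_retweet` metadata flag or a literal `RT @` text prefix.
- **Language** keeps only `lang == "en"`. Undetermined (`und`) or missing
  codes are removed: an English-only corpus cannot verify them, and no
  language detector is in scope.
- **Exclusion phrases** match as case-insensitive *contiguous substrings*
  of raw text. Consequently "nicotine stained" is removed because it
  contains "nicotine stain". One of the four shipped phrases ("silver
  spoon") does not itself contain the keyword, which only makes sense
  applied inside an already keyword-matched corpus — the cascade preserves
  that ordering.
- **Bot threshold** is inclusive: `score ≥ 4.0` on the 0–5 scale is a bot.
  Missing scores mean the account was deleted before scoring; its posts are
  dropped rather than guessed. Accounts absent from the score table are
  treated as missing and logged, not errored, since partial score tables
  are common in batch scoring.

## Normalization

Six transformations, applied in this order: URL removal; collapsing every
`@name` mention to the common token `@person` (counted in `n_mentions`);
hashtag handling; lower-casing with punctuation/special-character
stripping (only `[a-z0-9]` survives inside a token, which also removes
emoji and non-Latin symbols); stop-word removal; lemmatization. URLs,
mentions and hashtags must be handled before punctuation stripping — the
`@`/`#` markers are destroyed otherwise — and that is the only
self-consistent ordering of the six steps.

- **Hashtags**: the default (`hashtag_mode="remove"`) drops the whole
  token, reading "removal of hashtags" literally; `"strip"` keeps the word
  and removes only the marker. A documented consequence of the default: a
  post matched only via `#nicotine` normalizes to tokens lacking
  `nicotine`, which is why keyword filtering runs upstream on raw text.
- **`@person`** is protected from character stripping so it survives as a
  matchable token (the person-tagging topic matches exactly this token).
- **Stop words** ship as a plain-text standard English function-word list
  (`data/stopwords.txt`), configurable per run.
- **Lemmatization** is dictionary-based: an exception table for irregular
  forms (`data/lemma_exceptions.txt`) plus conservative suffix rules for
  regular plural/-ed/-ing inflection, with doubled-consonant undoing and
  final-e restoration (quitting → quit, vaping → vape, cigarettes →
  cigarette). Rules are iterated to a fixed point, making the lemmatizer —
  and therefore whole-text normalization — idempotent, which the suite
  checks on fixtures and on arbitrary generated text. The trade-off of a
  rule lemmatizer is occasional over- or under-stemming on open vocabulary;
  this cannot affect classification consistency because lexicon patterns
  are lemmatized *through the same function* when loaded. Token-for-token
  agreement with any other lemmatizer is explicitly not a goal, and no
  test depends on it.

## Topic lexicon and classifier

A topic is a nonempty list of patterns; a tweet receives every topic with
at least one matching pattern (multi-label, possibly empty; overlaps need
no tie-breaking by design). Pattern semantics: *unigram* = token
membership; *bigram* = adjacent ordered pair; *ordered group* = ordered
subsequence with gaps allowed. The distinction between bigrams and ordered
groups is exactly adjacency: "groups of words that must occur in a specific
order" allows intervening tokens. The matcher is checked against an
independent brute-force oracle (subsequence/window enumeration) on
randomized instances, and two monotonicity properties hold: adding a
pattern never removes a topic from any tweet, and adding tokens to a tweet
never removes a topic.

The shipped 15-topic lexicon is a **reconstruction** from published topic
descriptions; the original study's pattern lists are unpublished. Absolute
prevalences produced with it are therefore not comparable to the original
corpus values, and nothing in the acceptance machinery treats them as such.
The lexicon lives in an editable YAML file whose tokens may be written in
surface form — they are normalized on load.

Unclassified tweets (no pattern from any topic) form the reported
"unclassified" remainder; coverage + unclassified = 100% before rounding.

## Reporting

All internal arithmetic is on exact integer counts; percentages are
rounded **half-up to 2 decimal places** only at the reporting boundary,
matching printed-precision conventions. Prevalence of topic *t* in a
cohort of *N* posts is `100·n_t/N`; the overlap matrix cell *(i, j)* is
`100·|i ∩ j|/N`, making the matrix symmetric with diagonal equal to
prevalence and every off-diagonal cell bounded by its two diagonals.
Cohort comparison reports signed differences (nonbot − bot) ranked by
absolute value. Empty cohorts yield zero-count reports rather than
percentages (prevalence over zero posts is undefined and raises at the
operation level; the pipeline writes zeros instead of calling it).

## Synthetic corpus generator

The generator emulates the *structure* of a keyword-matched collection, not
its language: every tweet is filler text from a fixed neutral vocabulary
plus (for topic-bearing tweets) one lexicon pattern embedded as a
contiguous block, which satisfies unigram, bigram-adjacency and
ordered-group semantics at once. The keyword is guaranteed present in raw
text — as part of the embedded pattern when the pattern contains it,
otherwise inserted at the head of the text (occasionally in hashtag or
upper-case form). Head placement is deliberate: a trailing keyword could
complete another topic's ordered group (e.g. *quit … nicotine*) by
accident. Filler words are chosen so that no filler lemma collides with
any default-lexicon token; background tweets therefore classify to zero
topics.

Default composition mirrors the modelled study corpus: 65% retweets
(half flagged, half `RT @` prefixed, to exercise both detection paths), 4%
non-English (marked via the `lang` field — generating real foreign text is
out of scope), 2% lyric false positives (one of the four phrases embedded
verbatim), 12% deleted accounts, 6.6% bots among scored accounts. The
default topic mixture follows the relative prevalence ranking reported for
the nonbot cohort with ~20% unclassifiable background — a documented
convenience, since true pre-classification proportions are unknowable. Bot
scores are drawn uniformly on [4, 5] and nonbot scores on [0, 4), so the
inclusive threshold separates the cohorts unambiguously;
`bot_boundary_mass` optionally places bot scores at exactly 4.0 to test
the boundary. Each tweet has its own account, so account-level and
post-level fractions coincide; follower networks and posting cadence are
not modelled.

With probability `multi_topic_rate` a topic-bearing tweet gains a second,
distinct topic drawn from the mixture restricted to the remaining real
topics. The exact probability that a tweet's intended label set contains
topic *t* is then

```
P(t) = p_t + m · Σ_{s≠t} p_s · p_t / (R − p_s),    R = Σ_real p_r
```

implemented as `expected_topic_probability` and verified against a direct
simulation of the mechanism.

**What passing tests show, and what they do not.** Because patterns are
embedded by construction, classifier *recall* of intended topics is 100% on
generator output — the tests assert containment (assigned ⊇ intended) and
report, but do not assert, precision. Prevalence-recovery tests check the
classified count against the exact central 99% binomial interval at `P(t)`
on the kept nonbot cohort; they use mixtures whose patterns are
non-interacting (smoking/vaping/caffeine), since a rule lexicon
intrinsically cross-triggers where vocabularies overlap (a *cessation*
tweet saying "quit smoking" genuinely also mentions smoking — on real data
that is a feature of multi-label description, not an error, but it would
shift single-topic recovery counts). None of this says anything about
accuracy on real tweets, where topic signal is not planted by construction
and the lexicon's coverage of actual phrasing is the binding constraint.

## Problem sizes and determinism

Everything is deterministic given a seed (single `numpy` generator,
sequential draws; same seed → byte-identical corpora). The suite and the
acceptance script run on corpora of 300–2,000 tweets: at 2,000 tweets the
kept nonbot cohort is ~500 posts, large enough that the 99% binomial
recovery intervals are a few percentage points wide while the full suite
finishes in seconds. Larger corpora change nothing structurally — every
operation is linear in corpus size except the overlap matrix, which is
quadratic in the (fixed) number of topics.

## Known limitations

- The lexicon reconstruction bounds realism: real-world prevalence
  estimates are only as good as the supplied patterns.
- The rule lemmatizer over-stems occasional open-vocabulary words; this is
  cosmetic for n-gram tables and immaterial for classification (see above).
- Language filtering trusts the `lang` metadata; no detector is included.
- Bot stratification consumes external scores; the scoring model itself is
  out of scope, and score uncertainty is not propagated.
- No significance testing accompanies the cohort comparison; reported
  differences are descriptive.
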