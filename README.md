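# nicotweet

An infoveillance pipeline for studying public conversation about **nicotine**
on Twitter. It is written for tobacco-control and digital-epidemiology
researchers who have a keyword-matched collection of posts plus per-account
bot-likelihood scores, and who want a transparent, auditable path from raw
posts to per-topic prevalence estimates — stratified by whether the posting
account looks like a human or a social bot.

## What the pipeline does

1. **Filtering cascade** with a conserving ledger (`input = kept + removed`
   at every stage): keyword inclusion (`nicotine`, hashtag form included),
   retweet removal (so observations are independent posts), language filter
   (English only), and exclusion of song-lyric false positives (posts
   containing *bad nicotine*, *nicotine heroin*, *nicotine stain*, or
   *silver spoon* as contiguous substrings).
2. **Cohort partition** by an external bot score on a 0–5 scale: posts from
   deleted (unscorable) accounts are dropped; accounts with score ≥ 4 form
   the *bot* cohort, the rest the *nonbot* cohort. The threshold is
   inclusive: a score of exactly 4.0 is a bot.
3. **Six-step text normalization**: URL removal; collapsing every
   `@account_name` mention to the common token `@person`; hashtag removal;
   lower-casing with punctuation/special-character stripping; non-printable
   and emoji removal; stop-word removal and lemmatization.
4. **N-gram frequency analysis** (unigrams and bigrams) to surface the
   common words and phrases.
5. **Rule-based multi-label topic classification** into 15 topics
   (person tagging, addiction, appeal, NRT, vaping, smoking, nicotine
   health risks, withdrawal, quit nicotine, cessation, polysubstance use,
   caffeine, underage use, new products, and the a-priori topic
   *nicotine is safe*). A topic matches when any of its patterns matches:
   a **unigram** (token present), a **bigram** (tokens adjacent, in order),
   or an **ordered group** (tokens in order, gaps allowed).
6. **Reporting** per cohort: topic prevalence
   `p_t = 100 · n_t / N` (the share of the cohort's `N` posts assigned
   topic *t*), coverage (share with ≥ 1 topic), a symmetric 15×15
   topic-overlap matrix whose cell *(i, j)* is the percentage of the cohort
   assigned both topics (diagonal = prevalence), and a nonbot-vs-bot
   comparison ranked by absolute prevalence difference. Percentages are
   rounded half-up to 2 decimals only at the reporting boundary.

A **synthetic-corpus generator** produces keyword-matched tweets with known
ground truth (topic labels, bot status, retweet/language/lyric
contamination), so the whole pipeline is testable end to end without any
data download.

## Worked example

Generate a 2,000-tweet synthetic corpus and run the whole pipeline:

```bash
nicotweet simulate --n-tweets 2000 --seed 1 --out-dir sim
nicotweet run-all sim/tweets.jsonl sim/scores.csv --out-dir reports
```

which prints the filter ledger and cohort summaries:

```
{
  "input": 2000,
  "output": 573,
  "stages": {
    "keyword": 0,
    "retweets": 1320,
    "non_english": 23,
    "excluded_phrases": 8,
    "deleted_accounts": 76
  }
}
nonbot: n=536 coverage=80.04%
bot: n=37 coverage=78.38%
```

Of 2,000 collected posts, 1,320 retweets, 23 non-English posts and 8 lyric
false positives were removed, 76 posts came from deleted accounts, and the
surviving 573 posts split into 536 nonbot and 37 bot posts. 80.04% of the
nonbot cohort was classified into at least one of the 15 topics.
`reports/nonbot_stats.csv` then holds the per-topic prevalences —

```
topic,count,prevalence_pct
person tagging,122,22.76
addiction,65,12.13
appeal,22,4.10
NRT,41,7.65
vaping,57,10.63
```

— i.e. 122 of the 536 nonbot posts (22.76%) tag another account, and
`reports/cohort_comparison.csv` ranks nonbot-vs-bot differences:

```
topic,nonbot_pct,bot_pct,difference
quit nicotine,6.34,10.81,-4.47
nicotine health risks,6.53,2.7,3.83
caffeine,3.17,0.0,3.17
```

The same steps are available as library calls (`generate_corpus`,
`apply_filters`, `normalize_corpus`, `classify_corpus`, `cohort_stats`,
`compute_overlap_matrix`, …) — see `docs/methods.md` for the methodological
details and design choices.

The shipped topic lexicon (`src/nicotweet/data/lexicon.yml`) is a documented
reconstruction from published topic descriptions and is meant to be edited;
classification quality on real data depends entirely on the lexicon you
supply.

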