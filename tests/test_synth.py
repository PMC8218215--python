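"""Synthetic corpus generator: determinism, composition recovery, pattern
embedding guarantees, ground-truth recall."""

import numpy as np
import pytest
from scipy.stats import binom

from nicotweet import (
    LYRIC_PHRASES,
    SynthConfig,
    apply_filters,
    classify_corpus,
    embed_pattern,
    expected_topic_probability,
    generate_corpus,
    match_pattern,
    normalize_corpus,
    normalize_text,
)


def binom99(n, p):
    """Exact central 99% binomial interval on the count scale."""
    return binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SynthConfig(topic_mixture={"smoking": 0.3, "background": 0.5})

    def test_probabilities_in_unit_interval(self):
        with pytest.raises(ValueError):
            SynthConfig(bot_fraction=1.5)

    def test_unknown_topic_rejected_at_generation(self):
        cfg = SynthConfig(topic_mixture={"no such topic": 0.5, "background": 0.5})
        with pytest.raises(ValueError, match="absent from lexicon"):
            generate_corpus(cfg)


class TestDeterminismAndShape:
    def test_empty_corpus(self):
        tweets, scores, truth = generate_corpus(SynthConfig(n_tweets=0))
        assert tweets == [] and scores == {} and truth.topics == {}

    def test_same_seed_identical_output(self):
        a = generate_corpus(SynthConfig(n_tweets=120, seed=17))
        b = generate_corpus(SynthConfig(n_tweets=120, seed=17))
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2].topics == b[2].topics and a[2].account_status == b[2].account_status

    def test_every_tweet_contains_keyword_and_unique_ids(self):
        tweets, _, truth = generate_corpus(SynthConfig(n_tweets=200, seed=3))
        assert len({t.tweet_id for t in tweets}) == 200
        for t in tweets:
            assert "nicotine" in t.text.lower()
            assert t.tweet_id in truth.topics  # exactly once, by dict keys


class TestBotScores:
    def test_scores_respect_status_and_threshold_gap(self):
        tweets, scores, truth = generate_corpus(SynthConfig(n_tweets=400, seed=11))
        for t in tweets:
            status = truth.account_status[t.author_id]
            score = scores[t.author_id].score
            if status == "deleted":
                assert score is None
            elif status == "bot":
                assert 4.0 <= score <= 5.0
            else:
                assert 0.0 <= score < 4.0

    def test_boundary_mass_places_scores_exactly_at_threshold(self):
        cfg = SynthConfig(
            n_tweets=300, seed=2, bot_fraction=0.5, deleted_account_fraction=0.0,
            bot_boundary_mass=1.0,
        )
        _, scores, truth = generate_corpus(cfg)
        bots = [a for a, s in truth.account_status.items() if s == "bot"]
        assert bots and all(scores[a].score == 4.0 for a in bots)


class TestEmbedPattern:
    def test_every_default_pattern_survives_normalization(
        self, lexicon, stopwords, lemmatizer
    ):
        """Construction guarantee: embedding then normalizing matches the
        pattern under the classifier's own semantics."""
        rng = np.random.default_rng(0)
        for topic in lexicon.topics:
            for pattern in lexicon.patterns[topic]:
                text = embed_pattern("just thinking about stuff honestly", pattern, rng)
                tokens, _ = normalize_text(text, stopwords, lemmatizer)
                assert match_pattern(tokens, pattern), (topic, pattern, tokens)

    def test_deterministic_middle_insertion_without_rng(self, stopwords, lemmatizer):
        from nicotweet import TopicPattern

        text = embed_pattern("one two three four", TopicPattern("bigram", ("cold", "turkey")))
        tokens, _ = normalize_text(text, stopwords, lemmatizer)
        assert match_pattern(tokens, TopicPattern("bigram", ("cold", "turkey")))


class TestCompositionRecovery:
    def test_contamination_fractions_within_99pct_binomial(self):
        cfg = SynthConfig(n_tweets=2000, seed=4)
        _, _, truth = generate_corpus(cfg)
        n = cfg.n_tweets
        checks = {
            "retweet": (sum(f["retweet"] for f in truth.flags.values()), cfg.retweet_fraction),
            "non_english": (
                sum(f["non_english"] for f in truth.flags.values()),
                cfg.non_english_fraction,
            ),
            "lyric": (sum(f["lyric"] for f in truth.flags.values()), cfg.lyric_fraction),
            "deleted": (
                sum(s == "deleted" for s in truth.account_status.values()),
                cfg.deleted_account_fraction,
            ),
        }
        for name, (count, p) in checks.items():
            lo, hi = binom99(n, p)
            assert lo <= count <= hi, (name, count, p)

    def test_flags_are_realized_in_the_corpus(self):
        tweets, _, truth = generate_corpus(SynthConfig(n_tweets=300, seed=6))
        for t in tweets:
            flags = truth.flags[t.tweet_id]
            assert flags["retweet"] == (t.is_retweet or t.text.startswith("RT @"))
            assert flags["non_english"] == (t.lang != "en")
            assert flags["lyric"] == any(p in t.text.lower() for p in LYRIC_PHRASES)


class TestTopicRecovery:
    def test_recall_is_total_on_kept_nonbot_cohort(self, stopwords, lemmatizer, lexicon):
        """Every intended topic of every surviving tweet is recovered."""
        tweets, scores, truth = generate_corpus(SynthConfig(n_tweets=800, seed=1))
        part, _ = apply_filters(tweets, scores)
        norm = normalize_corpus(part.nonbot + part.bot, stopwords, lemmatizer)
        assignment = classify_corpus(norm, lexicon)
        for tweet_id, assigned in assignment.items():
            assert truth.topics[tweet_id] <= assigned

    @pytest.mark.parametrize("seed", [1, 2])
    def test_classified_prevalence_recovers_mixture(
        self, seed, stopwords, lemmatizer, lexicon
    ):
        """Non-interacting mixture: classified prevalence of each topic among
        kept nonbot tweets sits in the exact 99% binomial interval."""
        cfg = SynthConfig(
            n_tweets=2000,
            seed=seed,
            topic_mixture={"smoking": 0.3, "vaping": 0.2, "background": 0.5},
            multi_topic_rate=0.0,
        )
        tweets, scores, _ = generate_corpus(cfg)
        part, _ = apply_filters(tweets, scores)
        norm = normalize_corpus(part.nonbot, stopwords, lemmatizer)
        assignment = classify_corpus(norm, lexicon)
        n = len(part.nonbot)
        for topic, p in (("smoking", 0.3), ("vaping", 0.2)):
            count = sum(1 for topics in assignment.values() if topic in topics)
            lo, hi = binom99(n, p)
            assert lo <= count <= hi, (topic, count, n)

    def test_recovery_accounts_for_multi_topic_rate(self, stopwords, lemmatizer, lexicon):
        cfg = SynthConfig(
            n_tweets=2000,
            seed=8,
            topic_mixture={"smoking": 0.25, "vaping": 0.25, "caffeine": 0.1, "background": 0.4},
            multi_topic_rate=0.4,
        )
        tweets, scores, _ = generate_corpus(cfg)
        part, _ = apply_filters(tweets, scores)
        norm = normalize_corpus(part.nonbot, stopwords, lemmatizer)
        assignment = classify_corpus(norm, lexicon)
        n = len(part.nonbot)
        for topic in ("smoking", "vaping", "caffeine"):
            p = expected_topic_probability(cfg, topic)
            count = sum(1 for topics in assignment.values() if topic in topics)
            lo, hi = binom99(n, p)
            assert lo <= count <= hi, (topic, count, n, p)


class TestExpectedTopicProbability:
    def test_closed_form_matches_mechanism_simulation(self):
        mixture = {"smoking": 0.25, "vaping": 0.25, "caffeine": 0.1, "background": 0.4}
        cfg = SynthConfig(topic_mixture=mixture, multi_topic_rate=0.4, seed=0)
        rng = np.random.default_rng(123)
        names = list(mixture)
        probs = np.array([mixture[t] for t in names])
        reals = [t for t in names if t != "background"]
        n_sim = 40000
        counts = {t: 0 for t in reals}
        for _ in range(n_sim):
            primary = names[rng.choice(len(names), p=probs)]
            chosen = set() if primary == "background" else {primary}
            if chosen and rng.random() < cfg.multi_topic_rate:
                others = [t for t in reals if t != primary]
                w = np.array([mixture[t] for t in others])
                chosen.add(others[rng.choice(len(others), p=w / w.sum())])
            for t in chosen:
                counts[t] += 1
        for t in reals:
            assert counts[t] / n_sim == pytest.approx(
                expected_topic_probability(cfg, t), abs=0.01
            )

    def test_zero_rate_reduces_to_mixture_weight(self):
        cfg = SynthConfig(
            topic_mixture={"smoking": 0.3, "vaping": 0.2, "background": 0.5},
            multi_topic_rate=0.0,
        )
        assert expected_topic_probability(cfg, "smoking") == pytest.approx(0.3)

    def test_background_is_not_a_topic(self):
        with pytest.raises(ValueError):
            expected_topic_probability(SynthConfig(), "background")
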