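"""Synthetic tweet-corpus generator with known ground truth.

Emulates a keyword-matched collection: every tweet's raw text contains the
inclusion keyword (plain or hashtag form); configurable fractions of
retweets, non-English posts, song-lyric false positives, deleted accounts
and bot accounts; and tweets whose texts embed topic-lexicon patterns at
configurable mixture proportions (with an optional second topic).  Topic
and contamination labels are returned as ground truth so every downstream
stage can be checked against intent.

Default fractions follow the composition of the study corpus this pipeline
models (about 65% retweets, 4% non-English, 2% lyric false positives, 12%
deleted accounts, 6.6% bots among scored accounts); the default topic
mixture mirrors the relative prevalence ranking reported for the nonbot
cohort, with roughly a fifth of tweets left as unclassifiable background.

Bot accounts receive scores drawn uniformly on [4, 5] and nonbots on
[0, 4), so the inclusive threshold of 4 separates them unambiguously;
``bot_boundary_mass`` places bot scores at exactly 4.0 to exercise the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np

from .corpus import BotScore, RawTweet
from .topics import TopicLexicon, TopicPattern, load_lexicon

BACKGROUND = "background"

LYRIC_PHRASES = ("bad nicotine", "nicotine heroin", "nicotine stain", "silver spoon")

# Filler vocabulary: neutral words whose lemmas collide with no default
# lexicon token, so background tweets stay unclassifiable.
_FILLER = (
    "today", "really", "still", "feel", "week", "long", "work", "home",
    "friend", "honestly", "morning", "tonight", "weekend", "thinking",
    "little", "thing", "everyone", "right", "time", "year", "never",
    "always", "maybe", "actually", "pretty", "wild", "crazy", "mood",
    "vibe", "energy", "again", "though", "literally", "finally", "day",
)

_NON_ENGLISH_LANGS = ("es", "fr", "de", "pt", "ja", "und")

_DEFAULT_MIXTURE = {
    "person tagging": 0.20,
    "smoking": 0.10,
    "vaping": 0.10,
    "addiction": 0.10,
    "NRT": 0.06,
    "quit nicotine": 0.05,
    "nicotine health risks": 0.04,
    "underage use": 0.035,
    "caffeine": 0.027,
    "appeal": 0.023,
    "new products": 0.021,
    "cessation": 0.017,
    "withdrawal": 0.015,
    "polysubstance use": 0.012,
    "nicotine is safe": 0.005,
    BACKGROUND: 0.195,
}

_STUDY_START = datetime(2018, 9, 30, tzinfo=timezone.utc)
_STUDY_DAYS = 366


@dataclass
class SynthConfig:
    """Generator settings; defaults are the modelled study conditions."""

    n_tweets: int = 2000
    topic_mixture: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIXTURE))
    bot_fraction: float = 0.066
    retweet_fraction: float = 0.65
    non_english_fraction: float = 0.04
    lyric_fraction: float = 0.02
    deleted_account_fraction: float = 0.12
    multi_topic_rate: float = 0.25
    bot_boundary_mass: float = 0.0
    keyword: str = "nicotine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tweets < 0:
            raise ValueError("n_tweets must be >= 0")
        for name in (
            "bot_fraction",
            "retweet_fraction",
            "non_english_fraction",
            "lyric_fraction",
            "deleted_account_fraction",
            "multi_topic_rate",
            "bot_boundary_mass",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = sum(self.topic_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"topic mixture must sum to 1, got {total}")
        if any(p < 0 for p in self.topic_mixture.values()):
            raise ValueError("mixture probabilities must be nonnegative")

    @property
    def real_topics(self) -> list[str]:
        return [t for t in self.topic_mixture if t != BACKGROUND]


@dataclass
class GroundTruth:
    """Intended labels for a generated corpus."""

    topics: dict[str, frozenset[str]]  # tweet_id -> intended topic set
    account_status: dict[str, str]  # author_id -> "bot" | "nonbot" | "deleted"
    flags: dict[str, dict[str, bool]]  # tweet_id -> retweet / non_english / lyric


def expected_topic_probability(config: SynthConfig, topic: str) -> float:
    """Exact probability that a generated tweet's intended topic set contains
    ``topic``, accounting for the second-topic mechanism.

    The primary topic is drawn from the mixture (background included); with
    probability ``multi_topic_rate`` a tweet with a real primary topic s gains
    a second, distinct real topic drawn with probability proportional to the
    mixture restricted to the remaining real topics.
    """
    mix = config.topic_mixture
    if topic not in mix or topic == BACKGROUND:
        raise ValueError(f"not a real topic in this mixture: {topic!r}")
    p_t = mix[topic]
    real_mass = sum(mix[t] for t in config.real_topics)
    extra = 0.0
    for s in config.real_topics:
        if s == topic:
            continue
        rest = real_mass - mix[s]
        if rest > 0:
            extra += mix[s] * (p_t / rest)
    return p_t + config.multi_topic_rate * extra


# ---------------------------------------------------------------------------
# Text assembly
# ---------------------------------------------------------------------------

def _pattern_block(pattern: TopicPattern, rng: Optional[np.random.Generator]) -> list[str]:
    """Surface words realizing one pattern as a contiguous block."""
    words: list[str] = []
    for tok in pattern.tokens:
        if tok == "@person":
            if rng is None:
                words.append("@person")
            else:
                words.append(f"@user{int(rng.integers(0, 100000))}")
        else:
            words.append(tok)
    return words


def embed_pattern(
    base_text: str,
    pattern: TopicPattern,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Insert the pattern into the text so that, after normalization, the
    tweet matches it under the classifier's semantics.

    Pattern tokens are inserted contiguously at a word boundary (contiguity
    satisfies unigram, bigram-adjacency and ordered-group semantics alike).
    """
    if not pattern.tokens:
        raise ValueError("pattern must be nonempty")
    words = base_text.split()
    block = _pattern_block(pattern, rng)
    pos = len(words) // 2 if rng is None else int(rng.integers(0, len(words) + 1))
    return " ".join(words[:pos] + block + words[pos:])


def _decorate(word: str, rng: np.random.Generator) -> str:
    """Sprinkle capitalization, punctuation and the odd emoji over filler
    words so normalization has real work to do."""
    r = rng.random()
    if r < 0.08:
        word = word.capitalize()
    elif r < 0.12:
        word = word.upper()
    r = rng.random()
    if r < 0.08:
        word += rng.choice(["!", ",", "!!", "..."])
    elif r < 0.10:
        word += "❤️"  # heart emoji, stripped by normalization
    return word


def _keyword_surface(keyword: str, rng: np.random.Generator) -> str:
    r = rng.random()
    if r < 0.10:
        return "#" + keyword
    if r < 0.20:
        return keyword.capitalize()
    if r < 0.25:
        return keyword.upper()
    return keyword


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(
    config: SynthConfig,
    lexicon: Optional[TopicLexicon] = None,
) -> tuple[list[RawTweet], dict[str, BotScore], GroundTruth]:
    """Generate tweets, per-account bot scores and ground truth.

    Deterministic for a fixed seed.  Patterns are embedded from the given
    lexicon (default: the packaged one); the keyword, when not already part
    of an embedded pattern, is placed at the head of the text so that it
    cannot complete another topic's ordered group by accident.
    """
    lex = lexicon if lexicon is not None else load_lexicon()
    unknown = [t for t in config.real_topics if t not in lex.topics]
    if unknown:
        raise ValueError(f"mixture topics absent from lexicon: {unknown}")
    rng = np.random.default_rng(config.seed)

    topic_names = list(config.topic_mixture)
    topic_probs = np.array([config.topic_mixture[t] for t in topic_names])
    topic_probs = topic_probs / topic_probs.sum()

    tweets: list[RawTweet] = []
    scores: dict[str, BotScore] = {}
    truth = GroundTruth(topics={}, account_status={}, flags={})
    step = timedelta(days=_STUDY_DAYS) / max(config.n_tweets, 1)

    for i in range(config.n_tweets):
        tweet_id = f"t{i:06d}"
        author_id = f"acct{i:06d}"

        # account status and score
        if rng.random() < config.deleted_account_fraction:
            status, score = "deleted", None
        elif rng.random() < config.bot_fraction:
            status = "bot"
            if config.bot_boundary_mass > 0 and rng.random() < config.bot_boundary_mass:
                score = 4.0
            else:
                score = float(rng.uniform(4.0, 5.0))
        else:
            status = "nonbot"
            score = float(rng.uniform(0.0, 4.0))
            score = min(score, 3.9999999)
        truth.account_status[author_id] = status
        scores[author_id] = BotScore(author_id=author_id, score=score)

        # intended topics
        primary = topic_names[int(rng.choice(len(topic_names), p=topic_probs))]
        intended: set[str] = set() if primary == BACKGROUND else {primary}
        if intended and rng.random() < config.multi_topic_rate:
            others = [t for t in config.real_topics if t != primary]
            w = np.array([config.topic_mixture[t] for t in others])
            if len(others) > 0 and w.sum() > 0:
                second = others[int(rng.choice(len(others), p=w / w.sum()))]
                intended.add(second)

        # contamination flags
        is_rt = rng.random() < config.retweet_fraction
        non_en = rng.random() < config.non_english_fraction
        lyric = rng.random() < config.lyric_fraction

        # text assembly: filler, then pattern blocks, keyword first
        n_filler = int(rng.integers(4, 9))
        items: list[list[str]] = [
            [_decorate(str(w), rng)] for w in rng.choice(_FILLER, size=n_filler)
        ]
        blocks: list[list[str]] = []
        for topic in sorted(intended):
            pattern = lex.patterns[topic][int(rng.integers(0, len(lex.patterns[topic])))]
            blocks.append(_pattern_block(pattern, rng))
        if lyric:
            blocks.append(str(rng.choice(LYRIC_PHRASES)).split())
        for block in blocks:
            items.insert(int(rng.integers(0, len(items) + 1)), block)
        flat = [w for block in items for w in block]
        if config.keyword.lower() not in " ".join(flat).lower():
            flat.insert(0, _keyword_surface(config.keyword, rng))
        text = " ".join(flat)

        rt_flagged = False
        if is_rt:
            if rng.random() < 0.5:
                rt_flagged = True
            else:
                text = f"RT @user{int(rng.integers(0, 100000))} " + text

        lang = "en" if not non_en else str(rng.choice(_NON_ENGLISH_LANGS))
        created = _STUDY_START + step * i
        tweets.append(
            RawTweet(
                tweet_id=tweet_id,
                text=text,
                author_id=author_id,
                lang=lang,
                is_retweet=rt_flagged,
                created_at=created.strftime("%Y-%m-%dT%H:%M:%SZ"),
            )
        )
        truth.topics[tweet_id] = frozenset(intended)
        truth.flags[tweet_id] = {"retweet": is_rt, "non_english": non_en, "lyric": lyric}

    return tweets, scores, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Persist ground truth as CSV (tweet-level rows; account status joined in
    by the tweet's author via matching indices is not assumed — status gets
    its own column keyed by tweet index order)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tweet_id", "topics", "retweet", "non_english", "lyric"])
        for tweet_id in sorted(truth.topics):
            flags = truth.flags[tweet_id]
            writer.writerow(
                [
                    tweet_id,
                    "|".join(sorted(truth.topics[tweet_id])),
                    int(flags["retweet"]),
                    int(flags["non_english"]),
                    int(flags["lyric"]),
                ]
            )
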