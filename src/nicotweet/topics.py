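"""N-gram frequency analysis and the rule-based multi-label topic classifier.

A topic is defined by a list of matchable patterns.  A *unigram* pattern
matches when its token occurs anywhere in the normalized tweet; a *bigram*
when its two tokens occur adjacently in order; an *ordered group* when its
tokens occur in order but not necessarily contiguously (a subsequence).  A
tweet is assigned every topic for which at least one pattern matches, so
classification is multi-label and possibly empty.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .normalize import Lemmatizer, NormalizedTweet, normalize_text

PATTERN_KINDS = ("unigram", "bigram", "ordered_group")

TopicAssignment = dict[str, frozenset[str]]
"""Mapping tweet_id -> set of assigned topic names."""


class LexiconError(ValueError):
    """Invalid topic lexicon or pattern."""


@dataclass(frozen=True)
class TopicPattern:
    kind: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise LexiconError(f"unknown pattern kind {self.kind!r}")
        n = len(self.tokens)
        if self.kind == "unigram" and n != 1:
            raise LexiconError(f"unigram pattern must have 1 token, got {self.tokens!r}")
        if self.kind == "bigram" and n != 2:
            raise LexiconError(f"bigram pattern must have 2 tokens, got {self.tokens!r}")
        if self.kind == "ordered_group" and n < 2:
            raise LexiconError(
                f"ordered_group pattern needs >= 2 tokens, got {self.tokens!r}"
            )
        if any(not t for t in self.tokens):
            raise LexiconError(f"pattern contains empty token: {self.tokens!r}")


@dataclass(frozen=True)
class TopicLexicon:
    """Mapping from topic names to their patterns, in a stable topic order."""

    topics: tuple[str, ...]
    patterns: Mapping[str, tuple[TopicPattern, ...]]

    def __post_init__(self) -> None:
        if len(set(self.topics)) != len(self.topics):
            raise LexiconError("topic names must be unique")
        for name in self.topics:
            if not self.patterns.get(name):
                raise LexiconError(f"topic {name!r} has no patterns")

    def __iter__(self):
        return iter(self.topics)

    def __len__(self) -> int:
        return len(self.topics)


def load_lexicon(
    path: Optional[str | Path] = None,
    lemmatizer: Optional[Lemmatizer] = None,
    stopwords: Optional[frozenset[str]] = None,
) -> TopicLexicon:
    """Load a topic lexicon from YAML (default: the packaged 15-topic lexicon).

    Pattern tokens are passed through the same normalization pipeline as
    tweet text, so the lexicon file may use surface forms.
    """
    if path is None:
        raw = resources.files("nicotweet.data").joinpath("lexicon.yml").read_text("utf-8")
    else:
        raw = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(raw)
    if not isinstance(doc, dict) or "topics" not in doc:
        raise LexiconError("lexicon file must contain a top-level 'topics' mapping")
    lem = lemmatizer if lemmatizer is not None else Lemmatizer()
    stop = stopwords if stopwords is not None else frozenset()
    topics: list[str] = []
    patterns: dict[str, tuple[TopicPattern, ...]] = {}
    for topic, entries in doc["topics"].items():
        if not isinstance(entries, list) or not entries:
            raise LexiconError(f"topic {topic!r}: expected a nonempty pattern list")
        plist: list[TopicPattern] = []
        for entry in entries:
            if not isinstance(entry, dict) or len(entry) != 1:
                raise LexiconError(f"topic {topic!r}: malformed pattern entry {entry!r}")
            (kind, phrase), = entry.items()
            tokens, _ = normalize_text(str(phrase), stop, lem)
            if not tokens:
                raise LexiconError(
                    f"topic {topic!r}: pattern {phrase!r} normalizes to nothing"
                )
            if kind == "unigram" and len(tokens) != 1:
                raise LexiconError(
                    f"topic {topic!r}: unigram {phrase!r} normalizes to {tokens!r}"
                )
            plist.append(TopicPattern(kind=kind, tokens=tokens))
        topics.append(str(topic))
        patterns[str(topic)] = tuple(plist)
    return TopicLexicon(topics=tuple(topics), patterns=patterns)


# ---------------------------------------------------------------------------
# N-grams
# ---------------------------------------------------------------------------

def extract_ngrams(tokens: Sequence[str], n: int) -> list[tuple[str, ...]]:
    """All contiguous length-``n`` windows, in order; empty when the tweet has
    fewer than ``n`` tokens."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def ngram_frequency(
    corpus: Iterable[NormalizedTweet | Sequence[str]],
    n: int,
    top_k: int,
) -> list[tuple[str, int]]:
    """Ranked ``(n-gram, count)`` table over the corpus, space-joined n-grams,
    counts descending with lexicographic tie-break, at most ``top_k`` rows."""
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    counts: Counter[str] = Counter()
    for item in corpus:
        tokens = item.tokens if isinstance(item, NormalizedTweet) else item
        counts.update(" ".join(g) for g in extract_ngrams(tokens, n))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


# ---------------------------------------------------------------------------
# Pattern matching and classification
# ---------------------------------------------------------------------------

def match_pattern(tokens: Sequence[str], pattern: TopicPattern) -> bool:
    """Does the normalized token sequence match the pattern?"""
    if pattern.kind == "unigram":
        return pattern.tokens[0] in tokens
    if pattern.kind == "bigram":
        a, b = pattern.tokens
        return any(tokens[i] == a and tokens[i + 1] == b for i in range(len(tokens) - 1))
    # ordered_group: pattern tokens occur as a subsequence, gaps allowed
    it = iter(tokens)
    return all(p in it for p in pattern.tokens)


def classify_tweet(
    tweet: NormalizedTweet | Sequence[str], lexicon: TopicLexicon
) -> frozenset[str]:
    """Every topic with at least one matching pattern (multi-label)."""
    tokens = tweet.tokens if isinstance(tweet, NormalizedTweet) else tuple(tweet)
    return frozenset(
        topic
        for topic in lexicon.topics
        if any(match_pattern(tokens, p) for p in lexicon.patterns[topic])
    )


def classify_corpus(
    corpus: Iterable[NormalizedTweet], lexicon: TopicLexicon
) -> TopicAssignment:
    """One entry per tweet; deterministic given the lexicon."""
    return {t.tweet_id: classify_tweet(t, lexicon) for t in corpus}
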