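"""Text normalization: the six transformations applied before n-gram and
pattern analysis.

In order: (1) URL removal, (2) collapsing of account mentions to the common
token ``@person``, (3) hashtag handling, (4) basic normalization
(lower-casing; stripping punctuation, special and non-printable characters,
which also drops emoticons and non-Latin symbols), (5) stop-word removal,
(6) lemmatization.  URLs, mentions and hashtags are handled before
punctuation stripping because their ``@``/``#`` markers would otherwise be
destroyed; that ordering is the only self-consistent one.

The lemmatizer is dictionary-based: an exception table for irregular forms
shipped as package data, plus conservative suffix rules for regular plural,
past-tense and progressive inflection, iterated to a fixed point so that
lemmatization (and hence the whole normalization) is idempotent.  Topic
lexicon patterns are passed through the same function when loaded, so
matching is consistent whatever the lemmatizer outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional

from .corpus import RawTweet

MENTION_TOKEN = "@person"

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_VOWELS = "aeiou"
_KEEP_CHARS = frozenset("abcdefghijklmnopqrstuvwxyz0123456789")


@dataclass(frozen=True)
class NormalizedTweet:
    """Ordered token sequence after the six transformations."""

    tweet_id: str
    tokens: tuple[str, ...]
    n_mentions: int = 0


# ---------------------------------------------------------------------------
# Packaged word lists
# ---------------------------------------------------------------------------

def _read_wordlist(name: str) -> list[str]:
    text = resources.files("nicotweet.data").joinpath(name).read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_stopwords(path: Optional[str | Path] = None) -> frozenset[str]:
    """Load a stop-word list (one word per line); default is the packaged
    standard English list."""
    if path is None:
        words = _read_wordlist("stopwords.txt")
    else:
        words = [
            ln.strip()
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    return frozenset(w.lower() for w in words)


def load_lemma_exceptions(path: Optional[str | Path] = None) -> dict[str, str]:
    if path is None:
        lines = _read_wordlist("lemma_exceptions.txt")
    else:
        lines = [
            ln.strip()
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    table: dict[str, str] = {}
    for ln in lines:
        inflected, lemma = ln.split()
        table[inflected] = lemma
    return table


# ---------------------------------------------------------------------------
# Lemmatizer
# ---------------------------------------------------------------------------

class Lemmatizer:
    """Dictionary-based English lemmatizer (exceptions + suffix rules).

    Idempotent: ``lem(lem(w)) == lem(w)`` for every word, because rules are
    applied repeatedly until a fixed point.
    """

    def __init__(self, exceptions: Optional[dict[str, str]] = None):
        self.exceptions = dict(load_lemma_exceptions() if exceptions is None else exceptions)

    def __call__(self, word: str) -> str:
        prev = None
        while word != prev:
            prev = word
            word = self._step(word)
        return word

    def _step(self, w: str) -> str:
        if w in self.exceptions:
            return self.exceptions[w]
        if not w.isascii() or not w.isalpha():
            return w  # tokens with digits or markers (e.g. "@person") pass through
        n = len(w)
        if n >= 5 and w.endswith("ies"):
            return w[:-3] + "y"
        if w.endswith("sses"):
            return w[:-2]
        if n >= 4 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
            return w[:-1]
        if n >= 5 and w.endswith("ied"):
            return w[:-3] + "y"
        if n >= 5 and w.endswith("ed") and not w.endswith("eed"):
            return self._repair(w[:-2])
        if n >= 6 and w.endswith("ing"):
            return self._repair(w[:-3])
        return w

    @staticmethod
    def _repair(stem: str) -> str:
        """Undo consonant doubling / restore a dropped final 'e' after
        stripping -ed/-ing (quitting -> quit, vaping -> vape)."""
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] in "bdgkmnprt":
            return stem[:-1]
        if stem.endswith("s") and not stem.endswith("ss"):
            return stem + "e"  # releasing -> release
        if (
            len(stem) >= 2
            and stem[-1] not in _VOWELS + "wxy"
            and stem[-1].isalpha()
            and stem[-2] in _VOWELS
            and (len(stem) == 2 or stem[-3] not in _VOWELS)
        ):
            return stem + "e"  # vaping -> vape, craving -> crave
        return stem


# ---------------------------------------------------------------------------
# Normalization proper
# ---------------------------------------------------------------------------

def normalize_text(
    text: str,
    stopwords: frozenset[str] | set[str],
    lemmatizer: Callable[[str], str],
    hashtag_mode: str = "remove",
) -> tuple[tuple[str, ...], int]:
    """Apply the six transformations to one text.

    Returns ``(tokens, n_mentions)``; the token list may be empty.  With
    ``hashtag_mode="remove"`` (default) the whole hashtag token is dropped;
    ``"strip"`` keeps the word and removes only the ``#`` marker.
    """
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(f" {MENTION_TOKEN} ", text)
    tokens: list[str] = []
    n_mentions = 0
    for raw_tok in text.split():
        if raw_tok == MENTION_TOKEN:
            n_mentions += 1
            tokens.append(MENTION_TOKEN)
            continue
        if raw_tok.startswith("#"):
            if hashtag_mode == "remove":
                continue
            raw_tok = raw_tok.lstrip("#")
        tok = "".join(c for c in raw_tok.lower() if c in _KEEP_CHARS)
        if not tok or tok in stopwords:
            continue
        tok = lemmatizer(tok)
        if not tok or tok in stopwords:
            continue
        tokens.append(tok)
    return tuple(tokens), n_mentions


def normalize_tweet(
    tweet: RawTweet,
    stopwords: frozenset[str] | set[str],
    lemmatizer: Callable[[str], str],
    hashtag_mode: str = "remove",
) -> NormalizedTweet:
    tokens, n_mentions = normalize_text(tweet.text, stopwords, lemmatizer, hashtag_mode)
    return NormalizedTweet(tweet_id=tweet.tweet_id, tokens=tokens, n_mentions=n_mentions)


def normalize_corpus(
    corpus: Iterable[RawTweet],
    stopwords: frozenset[str] | set[str],
    lemmatizer: Callable[[str], str],
    hashtag_mode: str = "remove",
) -> list[NormalizedTweet]:
    """One NormalizedTweet per input tweet; ids and order preserved."""
    return [normalize_tweet(t, stopwords, lemmatizer, hashtag_mode) for t in corpus]
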