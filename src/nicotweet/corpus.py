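"""Core record types and file I/O for tweet corpora and bot scores.

Tweet corpora are stored as JSON-lines (one object per post), the way
Streaming-API dumps are conventionally kept; bot scores are a two-column
CSV (``author_id,score``) matching Botometer batch output, with a blank
score meaning the account was deleted before it could be scored.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional


class CorpusError(ValueError):
    """Malformed or inconsistent corpus input."""


BOT_SCORE_MIN = 0.0
BOT_SCORE_MAX = 5.0

_TWEET_FIELDS = ("tweet_id", "text", "author_id", "lang", "is_retweet", "created_at")


@dataclass(frozen=True)
class RawTweet:
    """One post as ingested, before any filtering.

    ``lang`` is a two-letter language code, or ``"und"`` when the language
    is undetermined. ``created_at`` is an ISO-8601 UTC timestamp string.
    """

    tweet_id: str
    text: str
    author_id: str
    lang: str = "und"
    is_retweet: bool = False
    created_at: str = "1970-01-01T00:00:00Z"

    def __post_init__(self) -> None:
        if not self.tweet_id:
            raise CorpusError("tweet_id must be nonempty")
        if not self.text:
            raise CorpusError(f"tweet {self.tweet_id}: text must be nonempty")


@dataclass(frozen=True)
class BotScore:
    """Per-account bot likelihood on the 0-5 Botometer scale.

    ``score`` is ``None`` for deleted / unscorable accounts.
    """

    author_id: str
    score: Optional[float]

    def __post_init__(self) -> None:
        if self.score is not None and not (BOT_SCORE_MIN <= self.score <= BOT_SCORE_MAX):
            raise CorpusError(
                f"account {self.author_id}: bot score {self.score} outside "
                f"[{BOT_SCORE_MIN}, {BOT_SCORE_MAX}]"
            )


@dataclass
class PipelineConfig:
    """Knobs for the end-to-end pipeline.

    Defaults reproduce the study conditions: the inclusion keyword
    ``nicotine`` (hashtag form included), the four song-lyric exclusion
    phrases, and the inclusive bot-score threshold of 4 out of 5.
    """

    keyword: str = "nicotine"
    exclusion_phrases: tuple[str, ...] = (
        "bad nicotine",
        "nicotine heroin",
        "nicotine stain",
        "silver spoon",
    )
    bot_threshold: float = 4.0
    stopword_path: Optional[str] = None  # None -> packaged English list
    lexicon_path: Optional[str] = None  # None -> packaged default lexicon
    hashtag_mode: str = "remove"  # "remove" whole token | "strip" the '#' marker
    top_k_ngrams: int = 25
    rounding: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (BOT_SCORE_MIN <= self.bot_threshold <= BOT_SCORE_MAX):
            raise CorpusError("bot_threshold must lie in [0, 5]")
        if self.rounding < 0:
            raise CorpusError("rounding must be >= 0")
        if self.hashtag_mode not in ("remove", "strip"):
            raise CorpusError("hashtag_mode must be 'remove' or 'strip'")
        if not self.keyword:
            raise CorpusError("keyword must be nonempty")


# ---------------------------------------------------------------------------
# Tweet corpus I/O (JSON-lines)
# ---------------------------------------------------------------------------

def read_tweets(path: str | Path) -> list[RawTweet]:
    """Read a JSON-lines tweet file, preserving file order.

    Raises :class:`CorpusError` naming the offending line for malformed
    records, and for duplicate ``tweet_id`` values.
    """
    tweets: list[RawTweet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: line {lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(obj, dict):
                raise CorpusError(f"{path}: line {lineno}: record is not an object")
            missing = [f for f in _TWEET_FIELDS if f not in obj]
            if missing:
                raise CorpusError(
                    f"{path}: line {lineno}: missing fields {', '.join(missing)}"
                )
            try:
                tweet = RawTweet(
                    tweet_id=str(obj["tweet_id"]),
                    text=str(obj["text"]),
                    author_id=str(obj["author_id"]),
                    lang=str(obj["lang"]),
                    is_retweet=bool(obj["is_retweet"]),
                    created_at=str(obj["created_at"]),
                )
            except CorpusError as exc:
                raise CorpusError(f"{path}: line {lineno}: {exc}") from exc
            if tweet.tweet_id in seen:
                raise CorpusError(
                    f"{path}: line {lineno}: duplicate tweet_id {tweet.tweet_id!r}"
                )
            seen.add(tweet.tweet_id)
            tweets.append(tweet)
    return tweets


def write_tweets(tweets: Iterable[RawTweet], path: str | Path) -> None:
    """Write a corpus as JSON-lines; round-trips field-by-field with read_tweets."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": t.tweet_id,
                        "text": t.text,
                        "author_id": t.author_id,
                        "lang": t.lang,
                        "is_retweet": t.is_retweet,
                        "created_at": t.created_at,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Bot-score I/O (CSV)
# ---------------------------------------------------------------------------

def read_bot_scores(path: str | Path) -> dict[str, BotScore]:
    """Read the ``author_id,score`` CSV; a blank score parses to missing."""
    scores: dict[str, BotScore] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return scores
        if [h.strip().lower() for h in header[:2]] != ["author_id", "score"]:
            raise CorpusError(f"{path}: expected header 'author_id,score', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise CorpusError(f"{path}: line {lineno}: expected 2 columns")
            author_id = row[0].strip()
            raw = row[1].strip()
            if raw == "":
                score: Optional[float] = None
            else:
                try:
                    score = float(raw)
                except ValueError as exc:
                    raise CorpusError(
                        f"{path}: line {lineno}: score {raw!r} is not numeric"
                    ) from exc
            try:
                scores[author_id] = BotScore(author_id=author_id, score=score)
            except CorpusError as exc:
                raise CorpusError(f"{path}: line {lineno}: {exc}") from exc
    return scores


def write_bot_scores(scores: Iterable[BotScore] | dict[str, BotScore], path: str | Path) -> None:
    if isinstance(scores, dict):
        scores = scores.values()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["author_id", "score"])
        for s in scores:
            writer.writerow([s.author_id, "" if s.score is None else repr(s.score)])
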