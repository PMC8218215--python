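"""The filtering cascade, with an auditable ledger.

Stage order follows the study design: keyword inclusion, retweet removal,
language filter, song-lyric phrase exclusion, then partition by bot score
(posts from deleted accounts dropped, the rest split into nonbot and bot
cohorts at an inclusive threshold).  Every stage records how many posts it
removed; the ledger must conserve counts exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .corpus import BotScore, PipelineConfig, RawTweet

logger = logging.getLogger(__name__)

STAGE_KEYWORD = "keyword"
STAGE_RETWEETS = "retweets"
STAGE_LANGUAGE = "non_english"
STAGE_PHRASES = "excluded_phrases"
STAGE_DELETED = "deleted_accounts"


@dataclass(frozen=True)
class LedgerEntry:
    stage: str
    removed: int


@dataclass
class FilterLedger:
    """Counts in, counts removed per stage, counts out; always conserving."""

    input_count: int
    stages: list[LedgerEntry] = field(default_factory=list)

    @property
    def output_count(self) -> int:
        return self.input_count - sum(e.removed for e in self.stages)

    def add(self, entry: LedgerEntry) -> None:
        if entry.removed < 0:
            raise ValueError(f"stage {entry.stage!r}: negative removal count")
        self.stages.append(entry)

    def check(self) -> None:
        remaining = self.input_count
        for e in self.stages:
            if e.removed < 0 or e.removed > remaining:
                raise ValueError(f"ledger violates conservation at stage {e.stage!r}")
            remaining -= e.removed
        assert remaining == self.output_count

    def rows(self) -> list[tuple[str, int, int]]:
        """(stage, removed, remaining) rows, starting from the input count."""
        out = []
        remaining = self.input_count
        for e in self.stages:
            remaining -= e.removed
            out.append((e.stage, e.removed, remaining))
        return out


@dataclass
class CohortPartition:
    """Disjoint split of the filtered corpus by account bot status."""

    nonbot: list[RawTweet]
    bot: list[RawTweet]
    dropped_deleted: list[RawTweet]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def keyword_filter(
    corpus: Sequence[RawTweet], keyword: str
) -> tuple[list[RawTweet], LedgerEntry]:
    """Keep tweets whose raw text contains the keyword case-insensitively;
    the hashtag form (``#`` + keyword) is thereby included as well."""
    if not keyword:
        raise ValueError("keyword must be nonempty")
    kw = keyword.lower()
    kept = [t for t in corpus if kw in t.text.lower()]
    return kept, LedgerEntry(STAGE_KEYWORD, len(corpus) - len(kept))


def _is_retweet(tweet: RawTweet) -> bool:
    return tweet.is_retweet or tweet.text.startswith("RT @")


def remove_retweets(corpus: Sequence[RawTweet]) -> tuple[list[RawTweet], LedgerEntry]:
    """Drop retweets (metadata flag or the conventional "RT @" text prefix)
    so each remaining observation is an independent post."""
    kept = [t for t in corpus if not _is_retweet(t)]
    return kept, LedgerEntry(STAGE_RETWEETS, len(corpus) - len(kept))


def filter_english(corpus: Sequence[RawTweet]) -> tuple[list[RawTweet], LedgerEntry]:
    """Keep only tweets marked English; undetermined ("und") counts as
    non-English because it cannot be verified."""
    kept = [t for t in corpus if t.lang == "en"]
    return kept, LedgerEntry(STAGE_LANGUAGE, len(corpus) - len(kept))


def remove_excluded_phrases(
    corpus: Sequence[RawTweet], phrases: Sequence[str]
) -> tuple[list[RawTweet], LedgerEntry]:
    """Drop tweets containing any exclusion phrase as a case-insensitive
    contiguous substring of the raw text (song-lyric false positives)."""
    if not phrases:
        raise ValueError("phrases must be nonempty")
    low = [p.lower() for p in phrases]
    kept = [t for t in corpus if not any(p in t.text.lower() for p in low)]
    return kept, LedgerEntry(STAGE_PHRASES, len(corpus) - len(kept))


def partition_by_bot_score(
    corpus: Sequence[RawTweet],
    scores: Mapping[str, BotScore],
    threshold: float,
) -> tuple[CohortPartition, LedgerEntry]:
    """Split by account: missing score -> dropped (deleted account);
    score >= threshold -> bot; score < threshold -> nonbot.

    Accounts absent from the score table are treated as missing and logged.
    """
    if not (0.0 <= threshold <= 5.0):
        raise ValueError(f"threshold {threshold} outside [0, 5]")
    nonbot: list[RawTweet] = []
    bot: list[RawTweet] = []
    dropped: list[RawTweet] = []
    unscored: set[str] = set()
    for t in corpus:
        entry = scores.get(t.author_id)
        if entry is None:
            unscored.add(t.author_id)
        if entry is None or entry.score is None:
            dropped.append(t)
        elif entry.score >= threshold:
            bot.append(t)
        else:
            nonbot.append(t)
    if unscored:
        logger.warning(
            "%d account(s) absent from the score table; their posts were "
            "treated as from deleted accounts",
            len(unscored),
        )
    partition = CohortPartition(nonbot=nonbot, bot=bot, dropped_deleted=dropped)
    return partition, LedgerEntry(STAGE_DELETED, len(dropped))


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------

def apply_filters(
    corpus: Sequence[RawTweet],
    scores: Mapping[str, BotScore],
    config: Optional[PipelineConfig] = None,
) -> tuple[CohortPartition, FilterLedger]:
    """Run all stages in study order and return cohorts plus the full ledger."""
    cfg = config if config is not None else PipelineConfig()
    ledger = FilterLedger(input_count=len(corpus))
    kept, entry = keyword_filter(corpus, cfg.keyword)
    ledger.add(entry)
    kept, entry = remove_retweets(kept)
    ledger.add(entry)
    kept, entry = filter_english(kept)
    ledger.add(entry)
    kept, entry = remove_excluded_phrases(kept, cfg.exclusion_phrases)
    ledger.add(entry)
    partition, entry = partition_by_bot_score(kept, scores, cfg.bot_threshold)
    ledger.add(entry)
    ledger.check()
    for stage, removed, remaining in ledger.rows():
        logger.info("stage %-18s removed=%d remaining=%d", stage, removed, remaining)
    return partition, ledger
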