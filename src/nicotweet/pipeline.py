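"""End-to-end pipeline: ingest -> filter cascade -> cohort partition ->
normalization -> n-gram tables -> topic classification -> reports.

All stage outputs are plain delimited text (CSV / JSON-lines) so runs can
be diffed; identical inputs and config produce identical files.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional

from .corpus import PipelineConfig, read_bot_scores, read_tweets, write_tweets
from .filters import CohortPartition, FilterLedger, apply_filters
from .normalize import Lemmatizer, NormalizedTweet, load_stopwords, normalize_corpus
from .report import CohortStats, cohort_stats, compare_cohorts, compute_overlap_matrix
from .topics import TopicAssignment, classify_corpus, load_lexicon, ngram_frequency

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Wraps a failure with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def write_ledger_csv(ledger: FilterLedger, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stage", "removed", "remaining"])
        writer.writerow(["input", 0, ledger.input_count])
        for stage, removed, remaining in ledger.rows():
            writer.writerow([stage, removed, remaining])


def write_normalized_jsonl(norm: list[NormalizedTweet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in norm:
            fh.write(
                json.dumps(
                    {"tweet_id": t.tweet_id, "tokens": list(t.tokens), "n_mentions": t.n_mentions}
                )
                + "\n"
            )


def write_assignment_csv(assignment: TopicAssignment, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tweet_id", "topics"])
        for tweet_id, topics in assignment.items():
            writer.writerow([tweet_id, "|".join(sorted(topics))])


def write_ngram_csv(table: list[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ngram", "count"])
        writer.writerows(table)


def write_stats_csv(stats: CohortStats, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic", "count", "prevalence_pct"])
        for topic, count in stats.topic_counts.items():
            writer.writerow([topic, count, f"{stats.prevalence_pct[topic]:.2f}"])
        writer.writerow(["__coverage__", "", f"{stats.coverage_pct:.2f}"])
        writer.writerow(["__unclassified__", "", f"{stats.unclassified_pct:.2f}"])
        writer.writerow(["__n_tweets__", stats.n_tweets, ""])


def run_pipeline(
    config: PipelineConfig,
    tweets_path: str | Path,
    scores_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """Run every stage in order and write the full report bundle.

    Returns a summary dict (ledger, per-cohort stats) for programmatic use.
    Any stage failure is re-raised as :class:`PipelineStageError` naming the
    stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(name, exc) from exc

    corpus = _stage("read_tweets", read_tweets, tweets_path)
    scores = _stage("read_bot_scores", read_bot_scores, scores_path)
    logger.info("read %d tweets, %d scored accounts", len(corpus), len(scores))

    partition, ledger = _stage("filter", apply_filters, corpus, scores, config)
    write_ledger_csv(ledger, out / "filter_ledger.csv")

    stopwords = _stage("load_stopwords", load_stopwords, config.stopword_path)
    lemmatizer = Lemmatizer()
    lexicon = _stage("load_lexicon", load_lexicon, config.lexicon_path, lemmatizer)

    summary = {
        "ledger": {"input": ledger.input_count, "output": ledger.output_count,
                   "stages": {e.stage: e.removed for e in ledger.stages}},
        "cohorts": {},
    }
    both: dict[str, CohortStats] = {}
    for cohort, tweets in (("nonbot", partition.nonbot), ("bot", partition.bot)):
        write_tweets(tweets, out / f"{cohort}_tweets.jsonl")
        norm = _stage(
            f"normalize[{cohort}]", normalize_corpus, tweets, stopwords, lemmatizer,
            config.hashtag_mode,
        )
        write_normalized_jsonl(norm, out / f"{cohort}_normalized.jsonl")
        for n, label in ((1, "unigrams"), (2, "bigrams")):
            table = _stage(f"ngrams[{cohort}]", ngram_frequency, norm, n, config.top_k_ngrams)
            write_ngram_csv(table, out / f"{cohort}_top_{label}.csv")
        assignment = _stage(f"classify[{cohort}]", classify_corpus, norm, lexicon)
        write_assignment_csv(assignment, out / f"{cohort}_topics.csv")
        stats = _stage(
            f"report[{cohort}]", cohort_stats, assignment, len(tweets), lexicon, cohort,
            config.rounding,
        )
        write_stats_csv(stats, out / f"{cohort}_stats.csv")
        if len(tweets) > 0:
            matrix = _stage(
                f"overlap[{cohort}]", compute_overlap_matrix, assignment, len(tweets),
                lexicon.topics, config.rounding,
            )
            matrix.to_csv(out / f"{cohort}_overlap.csv")
        both[cohort] = stats
        summary["cohorts"][cohort] = {
            "n_tweets": stats.n_tweets,
            "coverage_pct": stats.coverage_pct,
            "unclassified_pct": stats.unclassified_pct,
            "prevalence_pct": dict(stats.prevalence_pct),
            "topic_counts": dict(stats.topic_counts),
        }
        logger.info(
            "cohort %-6s n=%d coverage=%.2f%%", cohort, stats.n_tweets, stats.coverage_pct
        )

    comparison = _stage("compare_cohorts", compare_cohorts, both["nonbot"], both["bot"])
    comparison.to_csv(out / "cohort_comparison.csv", index=False)
    summary["comparison"] = comparison.to_dict(orient="records")
    return summary
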