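"""Per-cohort reporting: topic prevalence, coverage, the topic-overlap
(confusion) matrix, and the nonbot-vs-bot comparison.

All arithmetic is on exact integer counts; percentages are rounded half-up
(to 2 decimal places by default) only at the reporting boundary, matching
printed-precision conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .topics import TopicAssignment, TopicLexicon


def round_half_up(value: float | Decimal, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimal places (40.275 -> 40.28)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, n: int, ndigits: int = 2) -> float:
    return round_half_up(Decimal(100 * count) / Decimal(n), ndigits)


@dataclass(frozen=True)
class CohortStats:
    """Topic counts and percentages for one cohort (nonbot or bot)."""

    cohort: str
    n_tweets: int
    topic_counts: Mapping[str, int]
    prevalence_pct: Mapping[str, float]
    coverage_pct: float
    unclassified_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "topic": list(self.topic_counts),
                "count": [self.topic_counts[t] for t in self.topic_counts],
                "prevalence_pct": [self.prevalence_pct[t] for t in self.topic_counts],
            }
        )


def topic_count(assignment: TopicAssignment, topic: str) -> int:
    return sum(1 for topics in assignment.values() if topic in topics)


def compute_prevalence(
    assignment: TopicAssignment, n_tweets: int, topic: str, ndigits: int = 2
) -> float:
    """Percentage of the cohort assigned the topic: 100 * count / n_tweets."""
    if n_tweets <= 0:
        raise ValueError("prevalence undefined for an empty cohort")
    return _pct(topic_count(assignment, topic), n_tweets, ndigits)


def prevalence_from_counts(count: int, n_tweets: int, ndigits: int = 2) -> float:
    """Reporting arithmetic on explicit counts (e.g. published numerators)."""
    if n_tweets <= 0:
        raise ValueError("prevalence undefined for an empty cohort")
    if not (0 <= count <= n_tweets):
        raise ValueError("count must lie in [0, n_tweets]")
    return _pct(count, n_tweets, ndigits)


def compute_coverage(
    assignment: TopicAssignment, n_tweets: int, ndigits: int = 2
) -> tuple[float, float]:
    """(coverage %, unclassified %): tweets with >= 1 topic, and the exact
    complement, each rounded at the boundary."""
    if n_tweets <= 0:
        raise ValueError("coverage undefined for an empty cohort")
    covered = sum(1 for topics in assignment.values() if topics)
    coverage = _pct(covered, n_tweets, ndigits)
    unclassified = _pct(n_tweets - covered, n_tweets, ndigits)
    return coverage, unclassified


def coverage_from_counts(covered: int, n_tweets: int, ndigits: int = 2) -> tuple[float, float]:
    if n_tweets <= 0:
        raise ValueError("coverage undefined for an empty cohort")
    return _pct(covered, n_tweets, ndigits), _pct(n_tweets - covered, n_tweets, ndigits)


def compute_overlap_matrix(
    assignment: TopicAssignment,
    n_tweets: int,
    topics: Sequence[str],
    ndigits: int = 2,
) -> pd.DataFrame:
    """Symmetric topic-by-topic grid: cell (i, j) is the percentage of the
    cohort belonging to both topics; the diagonal is each topic's prevalence."""
    if n_tweets <= 0:
        raise ValueError("overlap matrix undefined for an empty cohort")
    topics = list(topics)
    counts = pd.DataFrame(0, index=topics, columns=topics, dtype=int)
    for assigned in assignment.values():
        present = [t for t in topics if t in assigned]
        for i in present:
            for j in present:
                counts.loc[i, j] += 1
    return counts.map(lambda c: _pct(int(c), n_tweets, ndigits))


def cohort_stats(
    assignment: TopicAssignment,
    n_tweets: int,
    lexicon: TopicLexicon,
    cohort: str,
    ndigits: int = 2,
) -> CohortStats:
    """Bundle counts, prevalences and coverage for one cohort.

    An empty cohort yields zero counts and zero percentages rather than
    raising, so reports can always be written.
    """
    counts = {t: topic_count(assignment, t) for t in lexicon.topics}
    if n_tweets == 0:
        prev = {t: 0.0 for t in lexicon.topics}
        return CohortStats(cohort, 0, counts, prev, 0.0, 0.0)
    prev = {t: _pct(counts[t], n_tweets, ndigits) for t in lexicon.topics}
    coverage, unclassified = compute_coverage(assignment, n_tweets, ndigits)
    return CohortStats(cohort, n_tweets, counts, prev, coverage, unclassified)


def compare_cohorts(nonbot: CohortStats, bot: CohortStats) -> pd.DataFrame:
    """Per-topic (nonbot %, bot %, signed difference), sorted by absolute
    difference descending, so the largest cohort contrasts rank first."""
    if set(nonbot.prevalence_pct) != set(bot.prevalence_pct):
        raise ValueError("cohorts cover different topic sets")
    rows = [
        {
            "topic": t,
            "nonbot_pct": nonbot.prevalence_pct[t],
            "bot_pct": bot.prevalence_pct[t],
            "difference": round_half_up(
                nonbot.prevalence_pct[t] - bot.prevalence_pct[t], 2
            ),
        }
        for t in nonbot.prevalence_pct
    ]
    frame = pd.DataFrame(rows)
    order = frame["difference"].abs().sort_values(ascending=False, kind="stable").index
    return frame.loc[order].reset_index(drop=True)


def export_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Optional heatmap rendering of an overlap matrix (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="% of cohort in both topics")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
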