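"""Cluster labeling from pile titles, rating aggregation, and pattern match.

Labeling mirrors how concept-mapping software suggests names: every
participant pile is scored against every cluster with the Jaccard
similarity |pile ∩ cluster| / |pile ∪ cluster| and, per cluster, piles are
ranked by score. Jaccard (rather than the overlap coefficient) penalizes
oversized piles, so a "lumper" pile covering half the map does not win
every cluster.

Rating aggregation follows the printed-table conventions of community
concept-mapping reports: a statement's importance is the arithmetic mean
of the available raters in scope (pairwise deletion of missing ratings), a
cluster's importance is the mean of its statements' means, and the
cluster SD is the population standard deviation (divide by n) of those
statement means. Arithmetic is at full precision; rounding (half-up, two
decimals) happens only at presentation.

The pattern match compares two stakeholder groups' cluster-mean vectors:
a ladder of per-group means, their Pearson correlation, and top-k overlap
counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .clustering import ClusterSolution
from .data import RatingRecord, SortRecord
from .errors import ComputationError, ValidationError


@dataclass(frozen=True)
class LabelCandidate:
    pile_label: str
    score: float
    sorter_id: str


@dataclass(frozen=True)
class ClusterRatingSummary:
    cluster: int
    scope: str
    statement_means: dict[int, float]
    cluster_mean: float
    cluster_sd: float

    @property
    def n_statements(self) -> int:
        return len(self.statement_means)


@dataclass(frozen=True)
class PatternMatch:
    clusters: tuple[int, ...]
    means_a: dict[int, float]
    means_b: dict[int, float]
    correlation: float
    order_a: tuple[int, ...]
    order_b: tuple[int, ...]
    top_k_overlap: dict[int, int]
    method: str = "pearson"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Presentation rounding (2.675 -> 2.68, unlike banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def suggest_labels(
    solution: ClusterSolution,
    sorts: Sequence[SortRecord],
    top_n: int | None = None,
) -> dict[int, list[LabelCandidate]]:
    """Rank participant pile titles against each cluster by Jaccard score.

    Piles with empty (whitespace-only) labels are excluded. Score ties are
    broken by how often the label string occurs across all sorters' piles
    (more frequent first), then lexicographically.
    """
    labeled = [
        (sort.sorter_id, label, members)
        for sort in sorts
        for label, members in sort.piles
        if label.strip()
    ]
    if not labeled:
        warnings.warn("no labeled piles: returning empty label suggestions",
                      stacklevel=2)
        return {c: [] for c in range(1, solution.k + 1)}
    label_freq = Counter(label for _, label, _ in labeled)

    out: dict[int, list[LabelCandidate]] = {}
    for cluster, members in solution.clusters().items():
        cluster_set = set(members)
        scored = []
        for sorter_id, label, pile in labeled:
            union = len(cluster_set | pile)
            score = len(cluster_set & pile) / union if union else 0.0
            scored.append(LabelCandidate(label, score, sorter_id))
        scored.sort(key=lambda c: (-c.score, -label_freq[c.pile_label],
                                   c.pile_label, c.sorter_id))
        out[cluster] = scored[:top_n] if top_n else scored
    return out


# ---------------------------------------------------------------------------
# Rating aggregation
# ---------------------------------------------------------------------------

def statement_means(
    ratings: Iterable[RatingRecord], scope: str = "all"
) -> dict[int, float]:
    """Mean importance per statement over the available raters in scope.

    ``scope`` is ``"all"`` (pool every rater) or a group name. Statements
    no in-scope rater rated are absent from the result.
    """
    records = [r for r in ratings if scope == "all" or r.group == scope]
    if not records:
        warnings.warn(f"no raters in scope {scope!r}", stacklevel=2)
        return {}
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for record in records:
        for sid, value in record.ratings.items():
            sums[sid] = sums.get(sid, 0.0) + value
            counts[sid] = counts.get(sid, 0) + 1
    return {sid: sums[sid] / counts[sid] for sid in sums}


def cluster_summary(
    solution: ClusterSolution,
    means: Mapping[int, float],
    scope: str = "all",
) -> list[ClusterRatingSummary]:
    """Per-cluster mean and population SD of the statement means."""
    summaries = []
    for cluster, members in solution.clusters().items():
        missing = [sid for sid in members if sid not in means]
        if missing:
            raise ComputationError(
                f"cluster {cluster}: no rating mean for statements {missing}"
            )
        values = np.array([means[sid] for sid in members], dtype=float)
        summaries.append(
            ClusterRatingSummary(
                cluster=cluster,
                scope=scope,
                statement_means={sid: means[sid] for sid in members},
                cluster_mean=float(values.mean()),
                cluster_sd=float(values.std(ddof=0)),
            )
        )
    return summaries


def summarize_ratings(
    solution: ClusterSolution,
    ratings: Iterable[RatingRecord],
    scope: str = "all",
) -> list[ClusterRatingSummary]:
    """statement_means + cluster_summary in one call."""
    return cluster_summary(solution, statement_means(ratings, scope), scope)


# ---------------------------------------------------------------------------
# Pattern match
# ---------------------------------------------------------------------------

def pattern_match(
    summaries_a: Sequence[ClusterRatingSummary],
    summaries_b: Sequence[ClusterRatingSummary],
    method: str = "pearson",
) -> PatternMatch:
    """Compare two groups' cluster-mean profiles.

    Returns the per-group means, their correlation (Pearson by default;
    Spearman behind the flag), each group's descending cluster ordering,
    and for every k the number of clusters shared by the two groups'
    top-k sets.
    """
    means_a = {s.cluster: s.cluster_mean for s in summaries_a}
    means_b = {s.cluster: s.cluster_mean for s in summaries_b}
    if set(means_a) != set(means_b):
        raise ValidationError(
            f"cluster sets differ: {sorted(means_a)} vs {sorted(means_b)}"
        )
    clusters = tuple(sorted(means_a))
    va = np.array([means_a[c] for c in clusters])
    vb = np.array([means_b[c] for c in clusters])
    if method == "pearson":
        corr = float(stats.pearsonr(va, vb).statistic) if len(clusters) > 1 else 1.0
    elif method == "spearman":
        corr = float(stats.spearmanr(va, vb).statistic) if len(clusters) > 1 else 1.0
    else:
        raise ValidationError(f"unknown correlation method {method!r}")

    # Descending by mean; ties broken by cluster index for determinism.
    order_a = tuple(sorted(clusters, key=lambda c: (-means_a[c], c)))
    order_b = tuple(sorted(clusters, key=lambda c: (-means_b[c], c)))
    overlap = {
        k: len(set(order_a[:k]) & set(order_b[:k]))
        for k in range(1, len(clusters) + 1)
    }
    return PatternMatch(
        clusters=clusters,
        means_a=means_a,
        means_b=means_b,
        correlation=corr,
        order_a=order_a,
        order_b=order_b,
        top_k_overlap=overlap,
        method=method,
    )
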