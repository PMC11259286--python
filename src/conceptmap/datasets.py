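"""Packaged reference data.

The package ships the printed outcome of a published community
concept-mapping study of barriers to starting and staying on medication
for opioid use disorder (MOUD): 70 participant-generated statements, their
final 7-cluster grouping, and each statement's mean importance rating on a
1-5 Likert scale pooled over 57 raters (23 consumers with lived experience
of opioid use disorder and 34 service providers). The raw sort and rating
records behind these summaries were never deposited, so this table is the
reference point for the rating-aggregation stages, while the synthetic
generator stands in for the raw records.
"""

from __future__ import annotations

import csv
from importlib import resources

from .data import Statement, StatementSet

_FIXTURE = "moud_barriers.csv"


def _rows() -> list[dict]:
    ref = resources.files(__package__) / "datasets" / _FIXTURE
    with ref.open(newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_moud_statements() -> StatementSet:
    """The 70-statement set, in printed ID order."""
    rows = sorted(_rows(), key=lambda r: int(r["statement_id"]))
    return StatementSet(Statement(int(r["statement_id"]), r["text"]) for r in rows)


def load_moud_cluster_assignment() -> dict[int, int]:
    """The published 7-cluster membership: statement_id -> cluster index."""
    return {int(r["statement_id"]): int(r["cluster"]) for r in _rows()}


def load_moud_cluster_labels() -> dict[int, str]:
    """Published cluster labels, e.g. 1 -> 'Availability and accessibility'."""
    return {int(r["cluster"]): r["cluster_label"] for r in _rows()}


def load_moud_statement_means() -> dict[int, float]:
    """Printed per-statement mean importance ratings (pooled, n = 57)."""
    return {int(r["statement_id"]): float(r["importance_mean"]) for r in _rows()}
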