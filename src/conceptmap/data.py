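"""Domain types and CSV I/O for statements, card sorts, and importance ratings.

Group concept mapping starts from three flat files:

* ``statements.csv`` — ``statement_id,text``; the brainstormed statement set.
* ``sorts.csv`` — ``sorter_id,pile_label,statement_id`` (long format, one
  row per card placement); each sorter's rows must form an exact partition
  of the statement set.
* ``ratings.csv`` — ``rater_id,group,statement_id,rating``; integer Likert
  ratings on a 1-5 importance scale, tagged with the rater's stakeholder
  group (``consumer``, ``provider`` or ``other``).

All files are UTF-8, RFC-4180 quoted, and statement IDs are carried
verbatim (the conventional 1-based numbering of the printed statement
list); internal array indexing never leaks into the data model.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    DuplicateRatingError,
    IncompleteSortError,
    PartitionError,
    ReferenceError_,
    ValidationError,
)

logger = logging.getLogger(__name__)

RATER_GROUPS = ("consumer", "provider", "other")
LIKERT_MIN, LIKERT_MAX = 1, 5


@dataclass(frozen=True)
class Statement:
    """One brainstormed statement, keyed by its printed ID."""

    statement_id: int
    text: str

    def __post_init__(self) -> None:
        if not isinstance(self.statement_id, int) or self.statement_id <= 0:
            raise ValidationError(
                f"statement_id must be a positive integer, got {self.statement_id!r}"
            )
        if not self.text.strip():
            raise ValidationError(
                f"statement {self.statement_id}: text is empty after trimming"
            )


class StatementSet:
    """An ordered collection of unique statements.

    Preserves file order; ``ids`` is the canonical row/column ordering used
    by every matrix downstream.
    """

    def __init__(self, statements: Iterable[Statement]):
        self.statements: tuple[Statement, ...] = tuple(statements)
        seen: set[int] = set()
        for s in self.statements:
            if s.statement_id in seen:
                raise ValidationError(f"duplicate statement_id {s.statement_id}")
            seen.add(s.statement_id)
        self._index = {s.statement_id: i for i, s in enumerate(self.statements)}

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(s.statement_id for s in self.statements)

    @property
    def size(self) -> int:
        return len(self.statements)

    def index_of(self, statement_id: int) -> int:
        try:
            return self._index[statement_id]
        except KeyError:
            raise ReferenceError_(f"unknown statement_id {statement_id}") from None

    def __len__(self) -> int:
        return self.size

    def __iter__(self):
        return iter(self.statements)

    def __contains__(self, statement_id: int) -> bool:
        return statement_id in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, StatementSet) and self.statements == other.statements


@dataclass(frozen=True, eq=False)
class SortRecord:
    """One participant's partition of the statement set into labeled piles.

    ``piles`` is an ordered tuple of ``(pile_label, members)`` pairs; labels
    are participant free text (possibly empty) and are preserved verbatim.
    Pile order carries no meaning, so equality compares piles as a set.
    """

    sorter_id: str
    piles: tuple[tuple[str, frozenset[int]], ...]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SortRecord):
            return NotImplemented
        return (self.sorter_id, frozenset(self.piles)) == (
            other.sorter_id, frozenset(other.piles)
        )

    def __hash__(self) -> int:
        return hash((self.sorter_id, frozenset(self.piles)))

    def validate(self, statements: StatementSet) -> None:
        """Enforce the exact-partition invariant against ``statements``."""
        seen: set[int] = set()
        for label, members in self.piles:
            if not members:
                raise PartitionError(f"sorter {self.sorter_id!r}: empty pile {label!r}")
            for sid in members:
                if sid not in statements:
                    raise ReferenceError_(
                        f"sorter {self.sorter_id!r}: unknown statement_id {sid}"
                    )
                if sid in seen:
                    raise PartitionError(
                        f"sorter {self.sorter_id!r}: statement {sid} appears in "
                        "more than one pile"
                    )
                seen.add(sid)
        missing = set(statements.ids) - seen
        if missing:
            raise IncompleteSortError(
                f"sorter {self.sorter_id!r}: statements not sorted: "
                f"{sorted(missing)}"
            )

    def pile_of(self, statement_id: int) -> str:
        for label, members in self.piles:
            if statement_id in members:
                return label
        raise ReferenceError_(
            f"sorter {self.sorter_id!r}: statement {statement_id} not in any pile"
        )

    def as_partition(self, statements: StatementSet) -> list[int]:
        """Pile index per statement, in statement-set order."""
        lookup = {sid: k for k, (_, members) in enumerate(self.piles) for sid in members}
        return [lookup[sid] for sid in statements.ids]


@dataclass(frozen=True)
class RatingRecord:
    """One rater's (possibly partial) importance ratings.

    ``ratings`` maps statement_id -> integer in [1, 5]; ``group`` tags the
    stakeholder group used for scoped summaries and the pattern match.
    """

    rater_id: str
    group: str
    ratings: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.group not in RATER_GROUPS:
            raise ValidationError(
                f"rater {self.rater_id!r}: group must be one of {RATER_GROUPS}, "
                f"got {self.group!r}"
            )
        for sid, value in self.ratings.items():
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValidationError(
                    f"rater {self.rater_id!r}: rating for statement {sid} "
                    f"is not an integer: {value!r}"
                )
            if not LIKERT_MIN <= value <= LIKERT_MAX:
                raise ValidationError(
                    f"rater {self.rater_id!r}: rating {value} for statement {sid} "
                    f"outside [{LIKERT_MIN}, {LIKERT_MAX}]"
                )

    def validate(self, statements: StatementSet) -> None:
        for sid in self.ratings:
            if sid not in statements:
                raise ReferenceError_(
                    f"rater {self.rater_id!r}: unknown statement_id {sid}"
                )


@dataclass
class StudyDataset:
    """A complete sort-and-rate dataset: statements, sorts, ratings.

    The sorter and rater ID namespaces are independent — in the motivating
    study consumers both sorted and rated while providers only rated.
    """

    statements: StatementSet
    sorts: tuple[SortRecord, ...] = ()
    ratings: tuple[RatingRecord, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sorts = tuple(self.sorts)
        self.ratings = tuple(self.ratings)
        for sort in self.sorts:
            sort.validate(self.statements)
        for rating in self.ratings:
            rating.validate(self.statements)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return (
            self.statements == other.statements
            and set(self.sorts) == set(other.sorts)
            and set((r.rater_id, r.group, tuple(sorted(r.ratings.items())))
                    for r in self.ratings)
            == set((r.rater_id, r.group, tuple(sorted(r.ratings.items())))
                   for r in other.ratings)
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_rows(path: Path | str, expected_header: list[str]) -> list[dict]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != expected_header:
            raise ValidationError(
                f"{path.name}: expected header {','.join(expected_header)!r}, "
                f"got {reader.fieldnames!r}"
            )
        return list(reader)


def _parse_int(raw: str, what: str, where: str) -> int:
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: {what} {raw!r} is not an integer") from None


def read_statements(path: Path | str) -> StatementSet:
    """Read ``statements.csv`` into a validated :class:`StatementSet`."""
    rows = _read_rows(path, ["statement_id", "text"])
    statements = [
        Statement(
            _parse_int(r["statement_id"], "statement_id", Path(path).name),
            (r["text"] or ""),
        )
        for r in rows
    ]
    return StatementSet(statements)


def read_sorts(
    path: Path | str,
    statements: StatementSet,
    *,
    on_incomplete: str = "strict",
) -> tuple[SortRecord, ...]:
    """Read long-format ``sorts.csv`` into one :class:`SortRecord` per sorter.

    ``on_incomplete`` controls the policy for sorters whose piles do not
    cover the full statement set: ``"strict"`` (default) raises
    :class:`IncompleteSortError`; ``"drop"`` discards the sorter with a
    logged warning. Disjointness violations are always errors.
    """
    if on_incomplete not in ("strict", "drop"):
        raise ValueError("on_incomplete must be 'strict' or 'drop'")
    rows = _read_rows(path, ["sorter_id", "pile_label", "statement_id"])
    by_sorter: dict[str, dict[str, set[int]]] = defaultdict(dict)
    order: list[str] = []
    for r in rows:
        sorter = r["sorter_id"]
        if sorter not in by_sorter:
            order.append(sorter)
        sid = _parse_int(r["statement_id"], "statement_id", Path(path).name)
        by_sorter[sorter].setdefault(r["pile_label"], set()).add(sid)

    records: list[SortRecord] = []
    for sorter in order:
        piles = tuple(
            (label, frozenset(members))
            for label, members in by_sorter[sorter].items()
        )
        record = SortRecord(sorter, piles)
        try:
            record.validate(statements)
        except IncompleteSortError:
            if on_incomplete == "drop":
                logger.warning("dropping incomplete sort from sorter %r", sorter)
                continue
            raise
        records.append(record)
    return tuple(records)


def read_ratings(path: Path | str, statements: StatementSet) -> tuple[RatingRecord, ...]:
    """Read long-format ``ratings.csv`` into one :class:`RatingRecord` per rater."""
    rows = _read_rows(path, ["rater_id", "group", "statement_id", "rating"])
    by_rater: dict[tuple[str, str], dict[int, int]] = {}
    order: list[tuple[str, str]] = []
    groups: dict[str, str] = {}
    for r in rows:
        rater = r["rater_id"]
        if rater in groups and groups[rater] != r["group"]:
            raise ValidationError(
                f"rater {rater!r}: conflicting groups "
                f"{groups[rater]!r} and {r['group']!r}"
            )
        groups[rater] = r["group"]
        key = (rater, r["group"])
        if key not in by_rater:
            by_rater[key] = {}
            order.append(key)
        sid = _parse_int(r["statement_id"], "statement_id", Path(path).name)
        if sid in by_rater[key]:
            raise DuplicateRatingError(
                f"rater {rater!r}: duplicate rating for statement {sid}"
            )
        by_rater[key][sid] = _parse_int(r["rating"], "rating", Path(path).name)

    records = []
    for rater, group in order:
        record = RatingRecord(rater, group, dict(by_rater[(rater, group)]))
        record.validate(statements)
        records.append(record)
    return tuple(records)


def read_dataset(
    directory: Path | str, *, on_incomplete: str = "strict"
) -> StudyDataset:
    """Read a canonical directory (statements/sorts/ratings CSVs) back in."""
    directory = Path(directory)
    statements = read_statements(directory / "statements.csv")
    sorts: tuple[SortRecord, ...] = ()
    ratings: tuple[RatingRecord, ...] = ()
    if (directory / "sorts.csv").exists():
        sorts = read_sorts(directory / "sorts.csv", statements,
                           on_incomplete=on_incomplete)
    if (directory / "ratings.csv").exists():
        ratings = read_ratings(directory / "ratings.csv", statements)
    return StudyDataset(statements, sorts, ratings)


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def write_dataset(dataset: StudyDataset, directory: Path | str) -> dict:
    """Write a dataset to ``directory`` in the canonical CSV dialects.

    Returns the manifest (also written as ``manifest.json``): file names,
    row counts, statement count, sorter count, and rater counts per group.
    Round-tripping through :func:`read_dataset` reproduces an equal dataset.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, int] = {}

    path = directory / "statements.csv"
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["statement_id", "text"])
        for s in dataset.statements:
            w.writerow([s.statement_id, s.text])
    files["statements.csv"] = dataset.statements.size

    path = directory / "sorts.csv"
    n = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sorter_id", "pile_label", "statement_id"])
        for sort in dataset.sorts:
            for label, members in sort.piles:
                for sid in sorted(members):
                    w.writerow([sort.sorter_id, label, sid])
                    n += 1
    files["sorts.csv"] = n

    path = directory / "ratings.csv"
    n = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["rater_id", "group", "statement_id", "rating"])
        for record in dataset.ratings:
            for sid in sorted(record.ratings):
                w.writerow([record.rater_id, record.group, sid, record.ratings[sid]])
                n += 1
    files["ratings.csv"] = n

    group_counts: dict[str, int] = defaultdict(int)
    for record in dataset.ratings:
        group_counts[record.group] += 1
    manifest = {
        "files": files,
        "n_statements": dataset.statements.size,
        "n_sorters": len(dataset.sorts),
        "n_raters_by_group": dict(group_counts),
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest


def data_quality_report(dataset: StudyDataset) -> dict:
    """Flag degenerate sorters (one pile, or all singletons).

    Degenerate sorts are retained by the pipeline — concept-mapping practice
    varies on whether "lumpers" and "splitters" are excluded — but they are
    surfaced here so analysts can decide.
    """
    one_pile = [s.sorter_id for s in dataset.sorts if len(s.piles) == 1]
    all_singletons = [
        s.sorter_id
        for s in dataset.sorts
        if len(s.piles) == dataset.statements.size
    ]
    if one_pile or all_singletons:
        warnings.warn(
            f"degenerate sorters retained: one-pile={one_pile}, "
            f"all-singletons={all_singletons}",
            stacklevel=2,
        )
    return {"one_pile": one_pile, "all_singletons": all_singletons}
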