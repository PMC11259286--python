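"""Co-occurrence similarity matrices from card sorts.

Each sorter contributes a binary S x S matrix whose (i, j) entry is 1 when
statements i and j share a pile (an equivalence relation: block-diagonal up
to reordering). Summing over sorters gives the aggregate similarity matrix
whose entries count how many of the N sorters co-piled each pair; values
range from 0 to N and the diagonal is exactly N. Ordination consumes a
dissimilarity transform of this matrix; because nonmetric MDS uses only the
rank order of dissimilarities, the count complement (N - s_ij) and the
proportion complement (1 - s_ij / N) yield identical configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data import SortRecord, StatementSet
from .errors import DegenerateInputError, ValidationError

TRANSFORMS = ("count_complement", "proportion_complement")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Aggregate statement x statement co-occurrence counts.

    Invariants: symmetric, integer, ``0 <= values <= n_sorters`` and
    ``values[i, i] == n_sorters``.
    """

    values: np.ndarray
    n_sorters: int
    statement_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = self.values
        s = len(self.statement_ids)
        if v.shape != (s, s):
            raise ValidationError(f"similarity matrix shape {v.shape} != ({s}, {s})")
        if not np.array_equal(v, v.T):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.array_equal(np.diag(v), np.full(s, self.n_sorters)):
            raise ValidationError("similarity diagonal must equal n_sorters")
        if v.min() < 0 or v.max() > self.n_sorters:
            raise ValidationError("similarity entries must lie in [0, n_sorters]")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Non-negative dissimilarities with zero diagonal, ready for ordination."""

    values: np.ndarray
    transform_tag: str
    statement_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = self.values
        if self.transform_tag not in TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform_tag!r}")
        if not np.allclose(v, v.T):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("dissimilarity diagonal must be zero")
        if v.min() < 0:
            raise ValidationError("dissimilarities must be non-negative")


def individual_matrix(sort: SortRecord, statements: StatementSet) -> np.ndarray:
    """Binary S x S co-membership matrix for one sorter (diagonal all 1)."""
    sort.validate(statements)
    s = statements.size
    out = np.zeros((s, s), dtype=np.int64)
    for _, members in sort.piles:
        idx = np.array([statements.index_of(sid) for sid in members])
        out[np.ix_(idx, idx)] = 1
    return out


def aggregate(
    matrices: Iterable[np.ndarray],
    statement_ids: Sequence[int],
) -> SimilarityMatrix:
    """Element-wise sum of individual sort matrices."""
    matrices = list(matrices)
    if not matrices:
        raise DegenerateInputError("no sort matrices to aggregate")
    shape = matrices[0].shape
    for m in matrices:
        if m.shape != shape:
            raise ValidationError(f"matrix shape mismatch: {m.shape} != {shape}")
    total = np.sum(matrices, axis=0, dtype=np.int64)
    return SimilarityMatrix(total, len(matrices), tuple(statement_ids))


def similarity_from_sorts(
    sorts: Sequence[SortRecord], statements: StatementSet
) -> SimilarityMatrix:
    """Convenience: individual matrices for every sorter, then aggregate."""
    if not sorts:
        raise DegenerateInputError("no sort records supplied")
    return aggregate(
        (individual_matrix(s, statements) for s in sorts), statements.ids
    )


def to_dissimilarity(
    sim: SimilarityMatrix, transform: str = "count_complement"
) -> DissimilarityMatrix:
    """Complement transform of an aggregate similarity matrix.

    ``count_complement``: d_ij = N - s_ij (range [0, N]);
    ``proportion_complement``: d_ij = 1 - s_ij / N (range [0, 1]).
    """
    if transform not in TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    if sim.n_sorters == 0:
        raise DegenerateInputError("cannot form dissimilarities with N = 0 sorters")
    if transform == "count_complement":
        values = (sim.n_sorters - sim.values).astype(float)
    else:
        values = 1.0 - sim.values / sim.n_sorters
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(values, transform, sim.statement_ids)


# ---------------------------------------------------------------------------
# TSV export / import (header row & column of statement IDs; JSON sidecar)
# ---------------------------------------------------------------------------

def write_similarity(sim: SimilarityMatrix, path: Path | str) -> None:
    path = Path(path)
    header = "\t".join(["statement_id"] + [str(i) for i in sim.statement_ids])
    lines = [header]
    for sid, row in zip(sim.statement_ids, sim.values):
        lines.append("\t".join([str(sid)] + [str(int(x)) for x in row]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"n_sorters": sim.n_sorters}), encoding="utf-8"
    )


def read_similarity(path: Path | str) -> SimilarityMatrix:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").strip().splitlines()
    ids = tuple(int(x) for x in lines[0].split("\t")[1:])
    values = np.array(
        [[int(x) for x in line.split("\t")[1:]] for line in lines[1:]],
        dtype=np.int64,
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    return SimilarityMatrix(values, int(meta["n_sorters"]), ids)
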