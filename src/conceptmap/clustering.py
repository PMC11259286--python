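"""Hierarchical clustering of the point map into candidate cluster solutions.

Statements are clustered on their 2D ordination coordinates — the map is
clustered, not the raw similarity matrix. The default criterion is Ward's:
each merge joins the pair of clusters with the smallest increase in total
within-cluster sum of squared Euclidean distances to the centroid (dESS).
For two clusters A and B this increase is

    dESS(A, B) = |A| |B| / (|A| + |B|) * ||centroid(A) - centroid(B)||^2,

which for two singletons is half their squared distance. Ward on Euclidean
distances is reducible, so merge heights never invert. Ties in dESS are
broken deterministically: merge the pair whose smallest contained statement
ID is lowest (then the partner's smallest ID). Clusters are numbered by the
lowest statement ID they contain, so solutions are comparable across runs.

Complete and average linkage are available behind a flag for sensitivity
analysis; the concept-mapping default is Ward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

LINKAGES = ("ward", "complete", "average")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step; clusters are named by lowest statement ID."""

    cluster_a: int
    cluster_b: int
    height: float
    new_size: int


@dataclass(frozen=True)
class MergeTree:
    merges: tuple[Merge, ...]
    statement_ids: tuple[int, ...]
    linkage: str = "ward"

    @property
    def size(self) -> int:
        return len(self.statement_ids)


@dataclass
class ClusterSolution:
    """A k-cluster partition of the statement set.

    ``assignment`` maps statement_id -> cluster index 1..k; ``labels`` maps
    cluster index -> ranked label candidates (filled by the interpretation
    stage; empty after a bare cut).
    """

    k: int
    assignment: dict[int, int]
    labels: dict[int, list] = field(default_factory=dict)

    def members(self, cluster: int) -> list[int]:
        return sorted(s for s, c in self.assignment.items() if c == cluster)

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {c: [] for c in range(1, self.k + 1)}
        for sid, c in self.assignment.items():
            out[c].append(sid)
        return {c: sorted(m) for c, m in out.items()}


def _pair_height(
    method: str,
    sa: int, sb: int,
    ca: np.ndarray, cb: np.ndarray,
    members_a: Sequence[int], members_b: Sequence[int],
    coords: np.ndarray, index: dict[int, int],
) -> float:
    if method == "ward":
        diff = ca - cb
        return float(sa * sb / (sa + sb) * np.dot(diff, diff))
    ia = [index[s] for s in members_a]
    ib = [index[s] for s in members_b]
    d = np.linalg.norm(coords[ia][:, None, :] - coords[ib][None, :, :], axis=2)
    return float(d.max() if method == "complete" else d.mean())


def linkage_tree(
    coordinates: np.ndarray,
    statement_ids: Sequence[int] | None = None,
    method: str = "ward",
) -> MergeTree:
    """Agglomerative merge tree on 2D (or any-dimensional) coordinates."""
    if method not in LINKAGES:
        raise ValidationError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValidationError("need an S x d coordinate matrix with S >= 2")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coordinates contain NaN or infinite values")
    s = coords.shape[0]
    ids = tuple(statement_ids) if statement_ids is not None else tuple(range(1, s + 1))
    if len(ids) != s:
        raise ValidationError("statement_ids length does not match coordinates")
    index = {sid: i for i, sid in enumerate(ids)}

    # Active clusters keyed by lowest contained statement ID.
    members: dict[int, list[int]] = {sid: [sid] for sid in ids}
    centroid: dict[int, np.ndarray] = {sid: coords[index[sid]].copy() for sid in ids}
    merges: list[Merge] = []
    while len(members) > 1:
        keys = sorted(members)
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                h = _pair_height(
                    method,
                    len(members[a]), len(members[b]),
                    centroid[a], centroid[b],
                    members[a], members[b], coords, index,
                )
                cand = (h, a, b)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        h, a, b = best
        merged = members[a] + members[b]
        sa, sb = len(members[a]), len(members[b])
        centroid[a] = (sa * centroid[a] + sb * centroid[b]) / (sa + sb)
        members[a] = merged
        del members[b], centroid[b]
        merges.append(Merge(a, b, h, len(merged)))
    return MergeTree(tuple(merges), ids, method)


def ward_tree(
    coordinates: np.ndarray, statement_ids: Sequence[int] | None = None
) -> MergeTree:
    """Ward (dESS) merge tree — the concept-mapping default."""
    return linkage_tree(coordinates, statement_ids, "ward")


def cut(tree: MergeTree, k: int) -> ClusterSolution:
    """The k-cluster partition obtained by undoing the last k - 1 merges."""
    s = tree.size
    if not 1 <= k <= s:
        raise ValidationError(f"k must lie in [1, {s}], got {k}")
    parent = {sid: sid for sid in tree.statement_ids}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for merge in tree.merges[: s - k]:
        ra, rb = find(merge.cluster_a), find(merge.cluster_b)
        root = min(ra, rb)  # cluster keeps its lowest statement ID
        parent[ra] = parent[rb] = root
    roots = sorted({find(sid) for sid in tree.statement_ids})
    number = {r: i + 1 for i, r in enumerate(roots)}
    assignment = {sid: number[find(sid)] for sid in tree.statement_ids}
    return ClusterSolution(k=k, assignment=assignment)


def solution_range(tree: MergeTree, k_min: int, k_max: int) -> list[ClusterSolution]:
    """One solution per k in [k_min, k_max], all cut from the same tree.

    Successive solutions nest: the k-solution refines the (k-1)-solution.
    """
    if not 1 <= k_min <= k_max <= tree.size:
        raise ValidationError(
            f"need 1 <= k_min <= k_max <= {tree.size}, got [{k_min}, {k_max}]"
        )
    solutions = [cut(tree, k) for k in range(k_min, k_max + 1)]
    for coarse, fine in zip(solutions, solutions[1:]):
        if not refines(fine, coarse):
            raise ValidationError(
                f"nesting violated between k={coarse.k} and k={fine.k}"
            )
    return solutions


def refines(fine: ClusterSolution, coarse: ClusterSolution) -> bool:
    """True if every cluster of ``fine`` lies inside one cluster of ``coarse``."""
    if set(fine.assignment) != set(coarse.assignment):
        return False
    image: dict[int, int] = {}
    for sid, c in fine.assignment.items():
        target = coarse.assignment[sid]
        if image.setdefault(c, target) != target:
            return False
    return True
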