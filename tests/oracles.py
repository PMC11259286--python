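"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity from its definition, by a route disjoint
from the package implementation: PAVA by explicit block pooling, Ward by
re-evaluating every candidate merge's ESS increase from scratch, and the
adjusted Rand index from the pair-counting contingency table.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb


def pava(values):
    """Pool-adjacent-violators by explicit block merging (O(n^2))."""
    blocks = [[float(v), 1] for v in values]  # [mean, count]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            m1, n1 = blocks[i]
            m2, n2 = blocks[i + 1]
            blocks[i] = [(m1 * n1 + m2 * n2) / (n1 + n2), n1 + n2]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for mean, count in blocks:
        out.extend([mean] * count)
    return np.array(out)


def ess(points: np.ndarray) -> float:
    """Within-cluster sum of squared distances to the centroid."""
    c = points.mean(axis=0)
    return float(((points - c) ** 2).sum())


def ward_merge_sequence(coords: np.ndarray, ids):
    """Greedy Ward agglomeration, recomputing ESS from scratch per pair.

    Ties broken by (smallest contained ID, partner's smallest ID), matching
    the documented rule. Returns [(id_a, id_b, delta_ess), ...].
    """
    coords = np.asarray(coords, float)
    index = {sid: i for i, sid in enumerate(ids)}
    clusters = {sid: [sid] for sid in ids}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                pa = coords[[index[s] for s in clusters[a]]]
                pb = coords[[index[s] for s in clusters[b]]]
                delta = ess(np.vstack([pa, pb])) - ess(pa) - ess(pb)
                cand = (delta, a, b)
                if best is None or cand < best:
                    best = cand
        delta, a, b = best
        merges.append((a, b, delta))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges


def adjusted_rand(labels_a, labels_b) -> float:
    """ARI from the pair-counting contingency table."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    cats_a = sorted(set(labels_a))
    cats_b = sorted(set(labels_b))
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[cats_a.index(x), cats_b.index(y)] += 1
    n = len(labels_a)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def kruskal_stress_reference(dmat: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 via the O(n^2) PAVA oracle and explicit pair enumeration."""
    n = dmat.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dist = np.array([np.linalg.norm(coords[i] - coords[j]) for i, j in pairs])
    dvals = np.array([dmat[i, j] for i, j in pairs])
    order = np.lexsort((dist, dvals))
    fitted = pava(dist[order])
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    return float(np.sqrt(((dhat - dist) ** 2).sum() / (dist**2).sum()))
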