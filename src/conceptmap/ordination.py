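"""Nonmetric multidimensional scaling with Kruskal stress-1.

The aggregate card-sort dissimilarities are embedded in the plane so that
the *rank order* of inter-point distances matches the rank order of the
dissimilarities as closely as possible. Fit quality is Kruskal's stress-1,

    stress = sqrt( sum_{i<j} (dhat_ij - dist_ij)^2 / sum_{i<j} dist_ij^2 ),

where ``dist`` are the configuration's Euclidean distances and ``dhat`` is
the least-squares monotone (isotonic) regression of the distances onto the
dissimilarity rank order. Stress 0 means a perfect rank fit; community
concept-mapping projects typically land between 0.10 and 0.35.

Optimization is iterative majorization (SMACOF-style): each cycle fits the
disparities ``dhat`` by monotone regression and then moves the
configuration by a Guttman transform. Ties in the dissimilarities are
handled by Kruskal's primary approach — tied dissimilarities may take
unequal fitted values (the tie block is ordered by current distance before
the monotone fit). The first start is classical (Torgerson) scaling of the
dissimilarities, which is deterministic and usually near-optimal; the
remaining starts are seeded random configurations guarding against local
minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .errors import ComputationError, DegenerateInputError, ValidationError
from .similarity import DissimilarityMatrix


@dataclass(frozen=True)
class MDSConfig:
    seed: int = 0
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-6


@dataclass(frozen=True)
class PointMap:
    """A canonicalized 2D configuration with its stress-1 value."""

    coordinates: np.ndarray
    stress: float
    statement_ids: tuple[int, ...]
    config: MDSConfig
    converged: bool
    n_iter: int = 0
    stress_trace: tuple[float, ...] = field(default=(), repr=False)


def monotone_regression(
    values: Sequence[float], tie_groups: Sequence[int] | None = None
) -> np.ndarray:
    """Least-squares non-decreasing fit (pool-adjacent-violators).

    ``values`` are ordered by dissimilarity rank. ``tie_groups``, if given,
    assigns each element a non-decreasing group id; within a tie group the
    values are re-ordered ascending before the fit (the primary approach,
    so tied dissimilarities may take unequal fitted values). The fitted
    values are returned in the original element order and preserve the
    input sum.
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise DegenerateInputError("monotone regression of an empty sequence")
    if tie_groups is None:
        order = np.arange(y.size)
    else:
        g = np.asarray(tie_groups)
        if g.shape != y.shape:
            raise ValidationError("tie_groups must match the value sequence length")
        if np.any(np.diff(g) < 0):
            raise ValidationError("tie_groups must be non-decreasing")
        order = np.lexsort((y, g))
    fit = isotonic_regression(y[order]).x
    out = np.empty_like(y)
    out[order] = fit
    return out


def _condensed(d: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    m = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, float)
    return squareform(m, checks=False)


def _fit_disparities(dvec: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Monotone fit of distances onto the dissimilarity rank order.

    Primary tie treatment: within a block of tied dissimilarities the
    distances are taken in ascending order, so ties impose no constraint.
    """
    order = np.lexsort((dist, dvec))
    fit = isotonic_regression(dist[order]).x
    dhat = np.empty_like(dist)
    dhat[order] = fit
    return dhat


def kruskal_stress(
    d: DissimilarityMatrix | np.ndarray, coordinates: np.ndarray
) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities."""
    dvec = _condensed(d)
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim != 2 or coordinates.shape[0] * (coordinates.shape[0] - 1) // 2 != dvec.size:
        raise ValidationError(
            f"coordinate shape {coordinates.shape} does not match "
            f"{dvec.size} dissimilarity pairs"
        )
    dist = pdist(coordinates)
    denom = float(np.dot(dist, dist))
    if denom == 0.0:
        raise DegenerateInputError("all points coincide: stress undefined")
    dhat = _fit_disparities(dvec, dist)
    return float(np.sqrt(np.sum((dhat - dist) ** 2) / denom))


def canonicalize(coordinates: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, and fix reflection signs.

    The configuration is translated to zero column means, rotated so the
    first principal axis is horizontal, and each axis is reflected so that
    the first point with a non-negligible coordinate on that axis is
    positive (in particular the first statement's x >= 0). Pairwise
    distances are unchanged; the map is idempotent.
    """
    x = np.asarray(coordinates, dtype=float)
    x = x - x.mean(axis=0)
    # Rotate onto principal axes via SVD of the centered configuration.
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        col = x[:, j]
        nz = np.nonzero(np.abs(col) > 1e-9)[0]
        if nz.size and col[nz[0]] < 0:
            x[:, j] = -col
    return x


def _classical_start(dmat: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering start (deterministic)."""
    d2 = dmat**2
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _guttman_step(x: np.ndarray, dhat: np.ndarray, pair_idx) -> np.ndarray:
    """One majorization update of the configuration toward the disparities."""
    n = x.shape[0]
    dist = pdist(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, dhat / dist, 0.0)
    b = np.zeros((n, n))
    iu, ju = pair_idx
    b[iu, ju] = -ratio
    b[ju, iu] = -ratio
    b[np.diag_indices(n)] = -b.sum(axis=1)
    return b @ x / n


def nonmetric_mds(
    d: DissimilarityMatrix | np.ndarray,
    dims: int = 2,
    *,
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    statement_ids: Sequence[int] | None = None,
) -> PointMap:
    """Nonmetric MDS of a dissimilarity matrix into ``dims`` dimensions.

    Runs ``n_starts`` independent optimizations (classical-scaling start
    first, then seeded random starts) and returns the lowest-stress
    configuration, canonicalized. Stress is non-increasing across the
    cycles of each run; a cycle that would raise stress is reverted and the
    run stops there. Identical inputs and seed give a bit-identical result.
    """
    if isinstance(d, DissimilarityMatrix):
        ids = d.statement_ids
        dmat = d.values
    else:
        dmat = np.asarray(d, dtype=float)
        ids = tuple(statement_ids) if statement_ids is not None else tuple(
            range(1, dmat.shape[0] + 1)
        )
    n = dmat.shape[0]
    if n < 3:
        raise ValidationError(f"nonmetric MDS needs at least 3 statements, got {n}")
    if not np.all(np.isfinite(dmat)):
        raise ValidationError("dissimilarities contain non-finite values")
    dvec = squareform(dmat, checks=False)
    if dvec.max() == 0:
        raise DegenerateInputError("all dissimilarities are zero")
    pair_idx = np.triu_indices(n, 1)
    rng = np.random.default_rng(seed)
    scale = dvec.mean()

    best: tuple[float, np.ndarray, bool, int, tuple[float, ...]] | None = None
    for start in range(max(1, n_starts)):
        if start == 0:
            x = _classical_start(dmat, dims)
            if np.allclose(x, 0):  # degenerate classical solution
                x = rng.uniform(-1, 1, size=(n, dims)) * scale
        else:
            x = rng.uniform(-1, 1, size=(n, dims)) * scale
        stress = kruskal_stress(dmat, x)
        trace = [stress]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            dist = pdist(x)
            dhat = _fit_disparities(dvec, dist)
            x_new = _guttman_step(x, dhat, pair_idx)
            try:
                stress_new = kruskal_stress(dmat, x_new)
            except DegenerateInputError:
                break
            if stress_new > stress:  # majorization stalled: keep the better map
                converged = True
                break
            x = x_new
            trace.append(stress_new)
            if stress > 0 and (stress - stress_new) / max(stress, 1e-30) < tol:
                stress = stress_new
                converged = True
                break
            stress = stress_new
            if stress < 1e-8:  # perfect rank fit
                converged = True
                break
        if best is None or stress < best[0]:
            best = (stress, x, converged, it, tuple(trace))

    assert best is not None
    stress, x, converged, n_iter, trace = best
    if not converged:
        warnings.warn(
            f"nonmetric MDS did not reach tol={tol} within {max_iter} iterations "
            f"(stress={stress:.4f})",
            stacklevel=2,
        )
    x = canonicalize(x)
    stress = kruskal_stress(dmat, x)
    if not 0.0 <= stress <= 1.0:
        raise ComputationError(f"stress {stress} outside [0, 1]")
    return PointMap(
        coordinates=x,
        stress=stress,
        statement_ids=ids,
        config=MDSConfig(seed=seed, n_starts=n_starts, max_iter=max_iter, tol=tol),
        converged=converged,
        n_iter=n_iter,
        stress_trace=trace,
    )
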