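"""Figures: point map, cluster map with convex hulls, pattern-match ladder.

SVG output is made deterministic (fixed hashsalt, no timestamp metadata),
so re-rendering identical inputs produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy.spatial import ConvexHull, QhullError  # noqa: E402

from .clustering import ClusterSolution
from .interpretation import ClusterRatingSummary
from .ordination import PointMap

_CLUSTER_COLORS = plt.get_cmap("tab10")


def _deterministic_save(fig, path: Path) -> None:
    with plt.rc_context({"svg.hashsalt": "conceptmap"}):
        fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def plot_point_map(point_map: PointMap, path: Path) -> None:
    """Each point is a statement, annotated with its ID."""
    fig, ax = plt.subplots(figsize=(7, 6))
    xy = point_map.coordinates
    ax.scatter(xy[:, 0], xy[:, 1], s=18, color="0.2", zorder=3)
    for sid, (x, y) in zip(point_map.statement_ids, xy):
        ax.annotate(str(sid), (x, y), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_title(f"Point map (stress = {point_map.stress:.4f})")
    ax.set_aspect("equal")
    _deterministic_save(fig, path)


def plot_cluster_map(
    point_map: PointMap, solution: ClusterSolution, path: Path
) -> None:
    """Point map overlaid with a convex hull per cluster."""
    fig, ax = plt.subplots(figsize=(7, 6))
    index = {sid: i for i, sid in enumerate(point_map.statement_ids)}
    for cluster, members in solution.clusters().items():
        pts = point_map.coordinates[[index[s] for s in members]]
        color = _CLUSTER_COLORS((cluster - 1) % 10)
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=color,
                   label=f"cluster {cluster}", zorder=3)
        if len(pts) >= 3:
            try:
                hull = ConvexHull(pts)
                poly = pts[np.append(hull.vertices, hull.vertices[0])]
                ax.fill(poly[:, 0], poly[:, 1], alpha=0.15, color=color)
                ax.plot(poly[:, 0], poly[:, 1], color=color, lw=1)
            except QhullError:
                ax.plot(pts[:, 0], pts[:, 1], color=color, lw=1)  # collinear
        elif len(pts) == 2:
            ax.plot(pts[:, 0], pts[:, 1], color=color, lw=1)
    for sid, (x, y) in zip(point_map.statement_ids, point_map.coordinates):
        ax.annotate(str(sid), (x, y), fontsize=6,
                    xytext=(2, 2), textcoords="offset points")
    ax.legend(fontsize=7, loc="best")
    ax.set_title(f"Cluster map (k = {solution.k})")
    ax.set_aspect("equal")
    _deterministic_save(fig, path)


def plot_pattern_match(
    summaries_a: list[ClusterRatingSummary],
    summaries_b: list[ClusterRatingSummary],
    path: Path,
    group_names: tuple[str, str] = ("consumer", "provider"),
) -> None:
    """Two vertical 1-5 axes with a line per cluster joining the group means."""
    means_a = {s.cluster: s.cluster_mean for s in summaries_a}
    means_b = {s.cluster: s.cluster_mean for s in summaries_b}
    fig, ax = plt.subplots(figsize=(5, 6))
    for cluster in sorted(means_a):
        color = _CLUSTER_COLORS((cluster - 1) % 10)
        ya, yb = means_a[cluster], means_b[cluster]
        ax.plot([0, 1], [ya, yb], marker="o", color=color, lw=1.5)
        ax.annotate(f"{cluster}", (0, ya), fontsize=8,
                    xytext=(-12, -3), textcoords="offset points", color=color)
        ax.annotate(f"{cluster}", (1, yb), fontsize=8,
                    xytext=(6, -3), textcoords="offset points", color=color)
    ax.set_xlim(-0.25, 1.25)
    ax.set_ylim(1, 5)
    ax.set_xticks([0, 1], group_names)
    ax.set_ylabel("mean cluster importance (1-5)")
    ax.set_title("Pattern match")
    _deterministic_save(fig, path)


def render_maps(
    point_map: PointMap,
    solution: ClusterSolution,
    summaries_a: list[ClusterRatingSummary] | None,
    summaries_b: list[ClusterRatingSummary] | None,
    output_dir: Path | str,
) -> dict[str, str]:
    """Write all applicable figures; returns {figure name: file name}."""
    output_dir = Path(output_dir)
    files: dict[str, str] = {}
    plot_point_map(point_map, output_dir / "point_map.svg")
    files["point_map_figure"] = "point_map.svg"
    plot_cluster_map(point_map, solution, output_dir / "cluster_map.svg")
    files["cluster_map_figure"] = "cluster_map.svg"
    if summaries_a and summaries_b:
        plot_pattern_match(
            summaries_a, summaries_b, output_dir / "pattern_match.svg"
        )
        files["pattern_match_figure"] = "pattern_match.svg"
    return files
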