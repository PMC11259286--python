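"""End-to-end pipeline: similarity -> MDS -> clustering -> labels -> ratings.

`run_pipeline` executes the full concept-mapping analysis on a canonical
input directory (statements/sorts/ratings CSVs), writes every stage's
export, and returns a JSON-serializable manifest that, together with the
seed it records, is sufficient to re-run the analysis bit-identically.
A ratings-only mode accepts a precomputed cluster assignment instead of
sorts, which is how published tables (whose raw sorts are unavailable)
are re-summarized.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import MergeTree, cut, solution_range, ward_tree
from .data import StudyDataset, read_dataset
from .errors import ComputationError, DegenerateInputError
from .interpretation import (
    ClusterRatingSummary,
    pattern_match,
    round_half_up,
    statement_means,
    suggest_labels,
    summarize_ratings,
)
from .ordination import PointMap, nonmetric_mds
from .similarity import similarity_from_sorts, to_dissimilarity, write_similarity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: Path | str
    output_dir: Path | str
    seed: int = 0
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    k: int = 7
    k_range: tuple[int, int] | None = None
    transform: str = "count_complement"
    scopes: tuple[str, ...] = ("all", "consumer", "provider")
    figures: bool = True
    on_incomplete: str = "strict"
    assignment_csv: Path | str | None = None  # ratings-only mode


def _write_csv(path: Path, header: list[str], rows) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def write_point_map(pm: PointMap, path: Path) -> None:
    _write_csv(
        path,
        ["statement_id", "x", "y"],
        [
            [sid, repr(float(x)), repr(float(y))]
            for sid, (x, y) in zip(pm.statement_ids, pm.coordinates)
        ],
    )


def write_tree(tree: MergeTree, path: Path) -> None:
    path.write_text(
        json.dumps(
            {
                "linkage": tree.linkage,
                "statement_ids": list(tree.statement_ids),
                "merges": [dataclasses.asdict(m) for m in tree.merges],
            },
            indent=2,
        ),
        encoding="utf-8",
    )


def write_summaries(summaries: list[ClusterRatingSummary], path: Path) -> None:
    _write_csv(
        path,
        ["cluster", "scope", "n_statements", "mean", "sd"],
        [
            [
                s.cluster,
                s.scope,
                s.n_statements,
                f"{round_half_up(s.cluster_mean):.2f}",
                f"{round_half_up(s.cluster_sd):.2f}",
            ]
            for s in summaries
        ],
    )


def table_report(
    summaries: list[ClusterRatingSummary],
    dataset: StudyDataset,
    labels: dict[int, list] | None = None,
) -> str:
    """Printed-table-style text report: cluster headers with statements."""
    text = {s.statement_id: s.text for s in dataset.statements}
    lines = []
    for s in sorted(summaries, key=lambda s: -s.cluster_mean):
        name = ""
        if labels and labels.get(s.cluster):
            name = f" — {labels[s.cluster][0].pile_label!r}"
        lines.append(
            f"Cluster {s.cluster}{name}: mean "
            f"{round_half_up(s.cluster_mean):.2f} "
            f"(SD {round_half_up(s.cluster_sd):.2f}), "
            f"{s.n_statements} statements"
        )
        for sid in sorted(s.statement_means):
            lines.append(
                f"  {sid:>3d}  {round_half_up(s.statement_means[sid]):.2f}"
                f"  {text.get(sid, '')}"
            )
        lines.append("")
    return "\n".join(lines)


def _read_assignment(path: Path | str) -> dict[int, int]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return {
            int(r["statement_id"]): int(r["cluster"]) for r in csv.DictReader(fh)
        }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all exports; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = read_dataset(config.input_dir, on_incomplete=config.on_incomplete)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "files": {},
    }
    files = manifest["files"]

    solution = None
    labels: dict[int, list] = {}
    if config.assignment_csv is not None:
        logger.info("ratings-only mode: using precomputed cluster assignment")
        assignment = _read_assignment(config.assignment_csv)
        from .clustering import ClusterSolution

        solution = ClusterSolution(
            k=len(set(assignment.values())), assignment=assignment
        )
        manifest["k"] = solution.k
    else:
        logger.info("stage: similarity (%d sorters)", len(dataset.sorts))
        if not dataset.sorts:
            raise DegenerateInputError("similarity stage: no sort records")
        sim = similarity_from_sorts(dataset.sorts, dataset.statements)
        write_similarity(sim, out / "similarity.tsv")
        files["similarity"] = "similarity.tsv"
        dis = to_dissimilarity(sim, config.transform)

        logger.info("stage: ordination (S=%d)", dataset.statements.size)
        pm = nonmetric_mds(
            dis,
            seed=config.seed,
            n_starts=config.n_starts,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        write_point_map(pm, out / "point_map.csv")
        (out / "mds_meta.json").write_text(
            json.dumps(
                {
                    "stress": pm.stress,
                    "seed": config.seed,
                    "n_starts": config.n_starts,
                    "iterations": pm.n_iter,
                    "converged": pm.converged,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        files["point_map"] = "point_map.csv"
        manifest["stress"] = pm.stress
        manifest["converged"] = pm.converged

        logger.info("stage: clustering (k=%d)", config.k)
        tree = ward_tree(pm.coordinates, dataset.statements.ids)
        write_tree(tree, out / "tree.json")
        files["tree"] = "tree.json"
        if config.k_range is not None:
            for sol in solution_range(tree, *config.k_range):
                path = out / f"solution_k{sol.k}.csv"
                _write_csv(
                    path,
                    ["statement_id", "cluster"],
                    sorted(sol.assignment.items()),
                )
                files[f"solution_k{sol.k}"] = path.name
        solution = cut(tree, config.k)
        manifest["k"] = config.k

        logger.info("stage: labeling")
        suggestions = suggest_labels(solution, dataset.sorts, top_n=5)
        labels = suggestions
        solution.labels = {c: list(s) for c, s in suggestions.items()}
        (out / "labels.json").write_text(
            json.dumps(
                {
                    str(c): [dataclasses.asdict(cand) for cand in cands]
                    for c, cands in suggestions.items()
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        files["labels"] = "labels.json"

    _write_csv(
        out / "solution.csv", ["statement_id", "cluster"],
        sorted(solution.assignment.items()),
    )
    files["solution"] = "solution.csv"
    manifest["clusters"] = {
        str(c): members for c, members in solution.clusters().items()
    }

    summaries_by_scope: dict[str, list[ClusterRatingSummary]] = {}
    if dataset.ratings:
        logger.info("stage: rating summaries")
        present_groups = {r.group for r in dataset.ratings}
        for scope in config.scopes:
            if scope != "all" and scope not in present_groups:
                continue
            try:
                summaries = summarize_ratings(solution, dataset.ratings, scope)
            except ComputationError:
                # scope lacks coverage of some statements; skip it
                logger.warning("scope %r lacks full statement coverage", scope)
                continue
            summaries_by_scope[scope] = summaries
            write_summaries(summaries, out / f"summary_{scope}.csv")
            files[f"summary_{scope}"] = f"summary_{scope}.csv"
        if "all" in summaries_by_scope:
            (out / "table_report.txt").write_text(
                table_report(summaries_by_scope["all"], dataset, labels),
                encoding="utf-8",
            )
            files["table_report"] = "table_report.txt"

        if "consumer" in summaries_by_scope and "provider" in summaries_by_scope:
            logger.info("stage: pattern match")
            pm_result = pattern_match(
                summaries_by_scope["consumer"], summaries_by_scope["provider"]
            )
            _write_csv(
                out / "pattern_match.csv",
                ["cluster", "consumer_mean", "provider_mean"],
                [
                    [
                        c,
                        f"{round_half_up(pm_result.means_a[c]):.2f}",
                        f"{round_half_up(pm_result.means_b[c]):.2f}",
                    ]
                    for c in pm_result.clusters
                ],
            )
            (out / "pattern_match.json").write_text(
                json.dumps(
                    {
                        "correlation": pm_result.correlation,
                        "order_consumer": list(pm_result.order_a),
                        "order_provider": list(pm_result.order_b),
                        "top_k_overlap": {
                            str(k): v for k, v in pm_result.top_k_overlap.items()
                        },
                    },
                    indent=2,
                ),
                encoding="utf-8",
            )
            files["pattern_match"] = "pattern_match.csv"
            manifest["pattern_match_correlation"] = pm_result.correlation

    if config.figures and config.assignment_csv is None and dataset.sorts:
        from .plots import render_maps

        figure_files = render_maps(
            pm,
            solution,
            summaries_by_scope.get("consumer"),
            summaries_by_scope.get("provider"),
            out,
        )
        files.update(figure_files)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    return manifest
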