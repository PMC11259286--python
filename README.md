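# conceptmap

Group concept mapping (CM) is a participatory mixed-methods technique used
widely in community health research: community members brainstorm
statements about a focus question, sort them into thematic piles, and rate
each statement's importance on a 1–5 Likert scale. Multivariate analysis
then turns the sorts into a 2D "concept map" of thematic clusters and the
ratings into cluster-level priority profiles per stakeholder group.

`conceptmap` implements that quantitative core as a tested Python library
for researchers who want a transparent, scriptable alternative to
proprietary CM software:

- **Similarity.** Each sorter's partition becomes a binary S×S
  co-membership matrix; summing over N sorters gives the aggregate
  similarity matrix T with T_ij ∈ [0, N] and T_ii = N. Ordination uses the
  complement D = N − T (or 1 − T/N; rank-equivalent).
- **Ordination.** Nonmetric multidimensional scaling into the plane,
  minimizing Kruskal's stress-1

  stress = √( Σ_{i<j} (d̂_ij − d_ij)² / Σ_{i<j} d_ij² ),

  where d are configuration distances and d̂ their least-squares monotone
  (isotonic) regression onto the dissimilarity rank order. The optimizer is
  SMACOF-style majorization alternated with monotone regression, with a
  deterministic classical-scaling first start plus seeded random restarts.
- **Clustering.** Ward hierarchical clustering of the map coordinates
  (ΔESS criterion, deterministic statement-ID tie-break), cut into the
  nested k = 6…8 solutions conventionally offered for interpretation.
- **Interpretation.** Cluster label suggestions ranked by Jaccard
  similarity between participant piles and clusters; per-statement and
  per-cluster importance means (population SD) overall and per rater
  group; a pattern match (per-group cluster means, Pearson correlation,
  top-k overlap).
- **Synthetic data.** A seeded generator with planted cluster structure and
  planted rating effects, plus a recovery report (adjusted Rand index,
  label recovery, stress) so every stage is testable without raw
  participant records.

The package ships one reference fixture: the printed statement table of a
published CM study of barriers to medication for opioid use disorder
(70 statements, 7 clusters, pooled importance means from 57 raters).

## Worked example

```python
import conceptmap as cm

dataset, truth = cm.generate_dataset(cm.SyntheticConfig(seed=7))
report = cm.recovery_report(dataset, truth, seed=7)
print(f"stress-1 = {report.stress:.4f}, ARI = {report.ari:.3f}, "
      f"label recovery = {report.label_recovery_rate:.2f}")
```

prints

```
stress-1 = 0.2025, ARI = 1.000, label recovery = 1.00
```

meaning: at the default study scale (70 statements, 23 sorters, moderate
sorter noise) the map fits the co-occurrence ranks with stress 0.20 —
inside the 0.10–0.35 band typical of CM projects — and the 7-cluster Ward
cut recovers the planted thematic partition exactly (adjusted Rand index
1.0), with every cluster's top suggested pile title carrying the planted
theme. Re-aggregating the packaged published table
(`examples/05_published_table.py`) reproduces the published cluster
importance means, from 4.05 ("Availability and accessibility") down to
3.44 ("Easier to use drugs").

The `examples/` directory has one short script per capability; the
`conceptmap` CLI exposes the same stages (`simulate`, `similarity`, `mds`,
`cluster`, `label`, `rate`, `patternmatch`, `run`, `report`) over the
canonical CSV/TSV/JSON files.

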