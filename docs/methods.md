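# Methods

## The analysis model

Group concept mapping turns K card-sort partitions and Likert ratings into
a clustered planar map of statements. The pipeline is:

1. **Co-occurrence similarity.** For sorter r, the binary matrix
   X^(r)_ij = 1 iff statements i and j share a pile (an equivalence
   relation, so each X^(r) is block-diagonal up to reordering). The
   aggregate T = Σ_r X^(r) counts co-piling sorters; T_ii = N and
   0 ≤ T_ij ≤ N. The dissimilarity for ordination is D = N − T by default
   (`count_complement`), with 1 − T/N available. Nonmetric MDS depends
   only on dissimilarity ranks, so the two transforms produce the same
   stress and the same configuration up to the overall scale factor N
   (property-tested).

2. **Nonmetric MDS (stress-1).** The configuration X ∈ R^{S×2} minimizes
   Kruskal's stress-1: with d_ij(X) the Euclidean distances and d̂ the
   least-squares non-decreasing fit of d onto the rank order of D,

   stress² = Σ_{i<j} (d̂_ij − d_ij)² / Σ_{i<j} d_ij².

   The diagonal is excluded (self-dissimilarity carries no information).
   Ties in D follow Kruskal's primary approach: a tied block is ordered by
   current distance before the isotonic fit, so tied dissimilarities may
   take unequal fitted values. The monotone fit itself is
   pool-adjacent-violators (via `scipy.optimize.isotonic_regression`); it
   conserves the sequence sum.

3. **Optimization.** Iterative majorization (SMACOF): each cycle refits d̂
   by monotone regression and applies a Guttman transform. The first of
   `n_starts = 10` starts is classical (Torgerson) scaling of D —
   deterministic and usually near-optimal; the rest are seeded uniform
   random configurations guarding against local minima. The lowest-stress
   start wins. Stopping: relative stress improvement < `tol = 1e-6`,
   stress < 1e-8 (perfect rank fit), or `max_iter = 500`; hitting the cap
   returns `converged=False` with a warning, never a silent failure.

   Majorization guarantees descent of *raw* stress, not of stress-1,
   whose denominator moves with the configuration. The optimizer
   therefore evaluates stress-1 after every full cycle and terminates,
   reverting the last update, if it would increase — so the recorded
   stress trace is non-increasing by construction. In practice such
   reverts occur only at convergence-level magnitudes.

4. **Canonical form.** Stress is invariant under rotation, translation,
   reflection and uniform scaling, so the returned map is canonicalized:
   centered, rotated to principal axes (first axis horizontal), and each
   axis reflected so its first non-negligible coordinate is positive.
   Distances are unchanged; the map is idempotent; fixed seed + input
   gives a bit-identical `PointMap`.

5. **Ward clustering of the map.** Clustering operates on the 2D
   coordinates, not the raw similarities — the convention of CM practice,
   which interprets the map. Merges minimize ΔESS =
   n_A n_B/(n_A+n_B)·‖c_A − c_B‖²; heights are ΔESS values and never
   invert (Ward is reducible). Equal-ΔESS ties merge the pair whose
   smallest contained statement ID is lowest, and clusters are numbered by
   their lowest statement ID, so solutions are stable across runs and
   rigid transforms of the map. Complete and average linkage exist behind
   a flag for sensitivity analysis only. The agglomeration is O(S³) by
   direct search — transparent, and instant at CM scales (S ≈ 70).

6. **Labels, ratings, pattern match.** Pile titles are ranked per cluster
   by Jaccard similarity |pile ∩ cluster|/|pile ∪ cluster| (penalizing
   oversized "lumper" piles; the overlap coefficient does not), ties
   broken by label frequency then lexicographically. A statement's
   importance is the mean over available in-scope raters (pairwise
   deletion of missing ratings); a cluster's mean is the unweighted mean
   of its statements' means, and its SD the population SD (divide by n)
   of those means — the convention that reproduces published CM tables.
   All arithmetic is full-precision; presentation rounds half-up to two
   decimals. The pattern match correlates two groups' cluster-mean
   vectors (Pearson; Spearman behind a flag) and reports descending
   orderings plus top-k overlaps.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `transform` | `count_complement` | dissimilarity convention; rank-equivalent to the proportion form |
| `n_starts` | 10 | MDS restarts (1 classical + 9 random) |
| `max_iter`, `tol` | 500, 1e-6 | per-start cycle cap and relative-improvement stop |
| `k`, `k_range` | 7, (6, 8) | cluster solutions offered for interpretation |
| `on_incomplete` | `strict` | incomplete sorts error; `drop` discards the sorter with a logged warning |

Incomplete sorts default to an error because in-person index-card sorting
produces complete partitions; the lenient flag exists for messy imports.
Degenerate sorters (one pile, or all singletons) are retained but flagged
by `data_quality_report` — CM practice varies and excluding them is an
analyst's call.

## The synthetic generator

`SyntheticConfig` defaults are the scale of the motivating study: S = 70
statements in K = 7 planted clusters (near-equal sizes), N = 23 sorters,
rater groups of 23 consumers and 34 providers. Sorter noise is
three-layered, mimicking documented lumper/splitter behavior: per-sorter
cluster split (prob 0.3) and merge (prob 0.3), then per-card jitter
ε = 0.15 (each card moves to a uniform different pile). A single-parameter
jitter cannot simultaneously produce realistic pile structure and stress
in the 0.10–0.35 band typical of CM studies; the three-layer defaults
land median stress ≈ 0.20 there. Ratings follow a discretized linear
model: group baseline (consumer 4.0, provider 3.6) + per-cluster offset
(+0.30 … −0.35, emulating the published spread of cluster means and
giving the groups a shared priority ordering) + per-statement effect
(SD 0.15) + rater noise (SD 0.8), rounded and clipped to [1, 5]. One
global seed feeds a named sub-stream per stage, so adding raters never
perturbs the sorts.

What passing the synthetic benchmarks shows: the pipeline recovers a
*planted block structure* under calibrated noise (median ARI ≥ 0.9 over
25 study-scale replicates; perfect recovery in the noiseless limit) and
its stress lands where real CM projects report it. What it does not show:
real sorters produce correlated, hierarchical, sometimes idiosyncratic
partitions with no single "true" k; bridging statements sitting between
themes (present in real maps) are not modeled; and Likert data from real
raters is not conditionally independent given cluster effects. Recovery
rates here are therefore an upper bound on what identical settings would
achieve on human data.

## Degenerate inputs and numerical edges

- All-equal dissimilarities: under primary tie treatment every
  configuration has stress 0; the classical start returns a symmetric
  (equilateral) layout.
- Duplicate map points are legal in clustering (ΔESS 0 merges first);
  NaN coordinates are rejected.
- An all-zero dissimilarity matrix, an empty sorter collection, or N = 0
  raise `DegenerateInputError` rather than producing silent nonsense.
- `kruskal_stress` refuses an all-coincident configuration (undefined
  denominator).
- Likert discretization is round-then-clip; an ordinal-threshold model
  was considered and rejected as an unneeded extra parameter layer.

## Known limitations

- The published study's stress value (0.3451) and its group-level rating
  ranges cannot be re-derived: the raw sort and rating records were never
  deposited, and the original software's MDS variant and tie policy are
  unspecified. The packaged fixture therefore pins only the arithmetic
  that is reproducible from printed values: all seven cluster means, and
  the SD cells (0.28, 0.32) that survive input rounding. Two printed SDs
  (0.29, 0.35) recompute to 0.30 and 0.36 from the rounded statement
  means — consistent with the original software aggregating unrounded
  means.
- Maps are fixed at 2 dimensions in the pipeline (the `dims` parameter
  exists); no individual-differences scaling, go-zone plots, bridging
  statistics, or automatic choice of k — k is an interpretive decision
  made with the community, not a statistic.
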