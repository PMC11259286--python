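"""From card sorts to a 2D point map.

Aggregates the sorters' pile co-occurrence counts into a similarity
matrix, complements it into dissimilarities, and embeds the statements in
the plane with nonmetric MDS. The stress-1 value says how faithfully the
map's distance ranks reproduce the co-occurrence ranks (community
concept-mapping projects typically land between 0.10 and 0.35).
"""

import conceptmap as cm

dataset, _ = cm.generate_dataset(cm.SyntheticConfig(seed=7))
sim = cm.similarity_from_sorts(dataset.sorts, dataset.statements)
print(f"similarity matrix: {sim.values.shape}, N = {sim.n_sorters} sorters")
print(f"most co-piled pair count: {sim.values[~(sim.values >= sim.n_sorters)].max()}")

point_map = cm.nonmetric_mds(cm.to_dissimilarity(sim), seed=7)
print(f"stress-1 = {point_map.stress:.4f} (converged: {point_map.converged})")
x, y = point_map.coordinates[0]
print(f"statement 1 sits at ({x:.2f}, {y:.2f}) in map units")
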