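"""Ward clustering of the point map and pile-title label suggestions.

The map coordinates are clustered hierarchically (Ward's minimum-variance
criterion) and cut into the 6-8 cluster solutions typically offered for
interpretation; each cluster's candidate names are the participant pile
titles most similar (Jaccard) to its membership.
"""

import conceptmap as cm

dataset, truth = cm.generate_dataset(cm.SyntheticConfig(seed=7))
d = cm.to_dissimilarity(cm.similarity_from_sorts(dataset.sorts, dataset.statements))
point_map = cm.nonmetric_mds(d, seed=7)

tree = cm.ward_tree(point_map.coordinates, dataset.statements.ids)
for solution in cm.solution_range(tree, 6, 8):
    sizes = sorted((len(m) for m in solution.clusters().values()), reverse=True)
    print(f"k = {solution.k}: cluster sizes {sizes}")

seven = cm.cut(tree, 7)
labels = cm.suggest_labels(seven, dataset.sorts, top_n=1)
for cluster in range(1, 8):
    top = labels[cluster][0]
    print(f"cluster {cluster}: top label {top.pile_label!r} "
          f"(Jaccard {top.score:.2f})")
# With the synthetic generator the labels carry the planted theme tags, so
# a 'cK theme' top label on cluster K means the theme was recovered.
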