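"""Generate a study-scale synthetic sort-and-rate dataset.

The defaults emulate a community concept-mapping study of barriers to
medication for opioid use disorder: 70 statements with 7 planted themes,
23 card sorters, and 57 raters in two stakeholder groups.
"""

from pathlib import Path

import conceptmap as cm

config = cm.SyntheticConfig(seed=7)
dataset, truth = cm.generate_dataset(config)
manifest = cm.write_dataset(dataset, Path("scratch/example_dataset"))

print(f"statements: {manifest['n_statements']}")
print(f"sorters:    {manifest['n_sorters']}")
print(f"raters:     {manifest['n_raters_by_group']}")
first = dataset.sorts[0]
print(f"{first.sorter_id} made {len(first.piles)} piles, "
      f"e.g. {first.piles[0][0]!r} with {len(first.piles[0][1])} cards")
# Pile labels carry the planted cluster tag (c1..c7), so downstream label
# suggestion can be scored against the ground truth in `truth`.
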