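"""Categorize connectomic signatures into functional-domain pairs.

Every node carries a major functional category (Action, Perception,
Cognition, Interoception, Emotion) and one of 53 nested subcategories;
each significant edge increments the cell of its endpoints' category
pair.  The 53x53 matrix aggregates exactly onto the 5x5 matrix.
"""

import numpy as np

from longconn import (
    aggregate_to_major,
    categorize_edges,
    generate_category_map,
    top_pairs,
)

cmap = generate_category_map(n_nodes=100, seed=4)
ids = list(cmap.major)

rng = np.random.default_rng(0)
signatures = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(40)]

sub = categorize_edges(signatures, cmap, level="sub")
major = aggregate_to_major(sub, cmap)
print(f"{sub.total} signatures categorized at both levels")
print(f"count conservation: 53x53 total = {int(sub.counts.to_numpy().sum())}, "
      f"5x5 total = {int(major.counts.to_numpy().sum())}")

ranked = top_pairs(major, k=5)
print("\nmost involved domain pairs (count, % of signatures):")
for r in ranked.itertuples(index=False):
    print(f"  {r.category_a:>13} - {r.category_b:<13} {r.count:>3}  {r.percent:5.1f}%")

ranked_sub = top_pairs(sub, k=3)
print("\nfinest-grained pairs driving the top domains:")
for r in ranked_sub.itertuples(index=False):
    print(f"  {r.category_a} - {r.category_b}: {r.count}")
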