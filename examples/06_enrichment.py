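"""Hypergeometric overrepresentation with a planted enriched gene set.

One set in the generated collection draws 60% of its members from the query
(e.g. the silenced-TF union); the ORA should give it the smallest BH q.
"""

import numpy as np

from omicnets import generate_gene_sets, hypergeometric_ora
from omicnets.enrich import GeneSetCollection, collapse_to_parents

rng = np.random.default_rng(3)
universe = [f"g{i:04d}" for i in range(1000)]
query = [str(g) for g in rng.choice(universe, size=60, replace=False)]
collection, truth = generate_gene_sets(universe, query, n_sets=20, set_size=50, seed=3)

result = hypergeometric_ora(set(query), set(universe), collection, min_overlap=2)
print("top 3 sets by BH q:")
print(result.head(3)[["k", "K", "odds_ratio", "p", "q"]].round(4).to_string())
print(f"planted enriched set: {truth.enriched_set}; "
      f"smallest q attained by: {result['q'].idxmin()}")

slim = collapse_to_parents(
    GeneSetCollection(
        sets={
            "Signal Transduction": ("Signal Transduction", frozenset({"a"})),
            "Signaling by GPCR": ("Signaling by GPCR", frozenset({"b", "c"})),
            "Signaling by Hedgehog": ("Signaling by Hedgehog", frozenset({"c", "d"})),
        },
        parents={
            "Signaling by GPCR": "Signal Transduction",
            "Signaling by Hedgehog": "Signal Transduction",
        },
    )
)
print("slim collapse:", {sid: sorted(slim.members(sid)) for sid in slim.sets})
# k of K members of a set overlap the n-gene query out of N universe genes;
# the upper hypergeometric tail is the chance of an overlap at least that
# large under random draws.
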