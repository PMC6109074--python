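"""Gene-set over-representation of a DEG list.

Builds a small universe with one truly enriched set, runs the upper-tail
hypergeometric test and prints the category-proportion breakdown.
"""

from permdeg import GeneSetCollection, category_proportions, hypergeom_enrich

universe = [f"gene{i}" for i in range(200)]
collection = GeneSetCollection(
    sets={
        "fatty_acid_oxidation": frozenset(universe[:20]),
        "glycolysis": frozenset(universe[20:45]),
        "ribosome_biogenesis": frozenset(universe[100:140]),
    },
).restrict_to(universe)

# a DEG list that mostly hits the first set
degs = universe[:15] + universe[150:155]
results = hypergeom_enrich(degs, collection)
print(results[["set_name", "overlap", "set_size", "p_value", "enriched"]])
print(
    "-> p_value is P(overlap >= observed) under random draws of "
    f"{len(degs)} genes from the {len(universe)}-gene universe"
)

props = category_proportions(degs, collection)
print("\nDEG category proportions (sum to 1, multi-membership split):")
print(props.round(3))
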