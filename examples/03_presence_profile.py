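"""Presence/absence profile of P450 families across a synthetic cohort.

Classifies four synthetic species, codes the species x family matrix as
3 (present) / -3 (absent), clusters both axes hierarchically under a
Euclidean metric, and reports co-presence counts — how many species carry
each family pair together.
"""

from cypcensus import (
    SyntheticSpeciesSpec,
    build_presence_matrix,
    classify_proteome,
    cluster_matrix,
    co_presence_counts,
    generate_reference_db,
    generate_species,
    per_species_family_counts,
)

REFS = ("CYP202A1", "CYP153A1", "CYP108A1", "CYP173A1")
refdb = generate_reference_db(REFS, length=420, seed=11)

cohort = [
    ("Alpha prima", (("CYP202A1", 0.9), ("CYP173A1", 0.8))),
    ("Alpha secunda", (("CYP202A1", 0.8), ("CYP173A1", 0.7), ("CYP153A1", 0.9))),
    ("Alpha tertia", (("CYP153A1", 0.85),)),
    ("Alpha quarta", (("CYP202A1", 0.7), ("CYP173A1", 0.9))),
]

db = refdb.copy()  # shared, so provisional names stay consistent cohort-wide
results = []
for i, (species, targets) in enumerate(cohort):
    records, _ = generate_species(
        SyntheticSpeciesSpec(species, targets, seed=100 + i), refdb
    )
    results.extend(classify_proteome(records, species, db))

matrix = cluster_matrix(build_presence_matrix(per_species_family_counts(results)))
print("presence matrix (3 = family present, -3 = absent):")
print(matrix.values.to_string())
print("\nrow order after clustering:", matrix.row_order)
print("column order after clustering:", matrix.col_order)

co = co_presence_counts(matrix)
print(f"\nspecies carrying both CYP202 and CYP173: {co.loc['202', '173']}")
print("(co-presence counts how often two families travel together)")
print("\nrow dendrogram (Newick):", matrix.row_newick())
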