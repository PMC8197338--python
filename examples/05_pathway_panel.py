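"""Homolog-based pathway presence call.

Searches a reference enzyme panel (think: the cholesterol side-chain
oxidation enzymes of a well-characterised organism) against a target
proteome by local alignment.  Each enzyme's best hit is scored on percent
identity, percent similarity ("homology") and query coverage; the pathway
is called present only when every enzyme has a passing homolog.  One
enzyme here has two planted homologs — both are reported, best first.
"""

from cypcensus import run_pathway_panel
from cypcensus.synthetic_data import mutate_to_identity, random_protein

panel = [
    (name, f"id{i}", random_protein(400, seed=200 + i))
    for i, name in enumerate(["cyp125", "fadD36", "fadE22", "echA9"])
]

proteome = [(f"decoy_{i}", random_protein(400, seed=300 + i)) for i in range(4)]
for i, (_, _, enzyme) in enumerate(panel):
    proteome.append((f"hom_{i}", mutate_to_identity(enzyme, 0.55, seed=400 + i)))
# a second, weaker homolog for fadD36 (as happens with paralogous ligases)
proteome.append(("hom_1_bis", mutate_to_identity(panel[1][2], 0.40, seed=500)))

report = run_pathway_panel(panel, proteome)

print(f"{'enzyme':<10}{'hit':<12}{'%id':>6}{'%hom':>7}{'qcov':>7}  verdict")
for (name, gid, _) in panel:
    for c in report.calls[gid]:
        print(f"{name:<10}{c.target_id:<12}{c.percent_identity:>6.0f}"
              f"{c.percent_similarity:>7.0f}{100 * c.query_cover:>6.0f}%"
              f"  {c.verdict}")

print(f"\n{report.n_present}/{report.n_reference_enzymes} enzymes with a "
      f"passing homolog -> pathway "
      f"{'present' if report.pathway_present else 'absent'}")
print("Thresholds default to identity>=25, similarity>=35, coverage>=50 —")
print("permissive on purpose, since distant organisms align at low identity.")
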