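"""Recompute the published cross-taxon census statistics.

Loads the packaged per-taxon integer inputs (species, P450, family and
BGC counts) and the published alphaproteobacterial family census, then
derives the comparative statistics with the census formulas.  The
printed values match the source tables: e.g. the alphaproteobacterial
diversity percentage 0.07 and BGC share 2.4%.
"""

from cypcensus.census_stats import (
    average_p450s,
    bgc_percentage,
    diversity_percentage,
    load_published_family_census,
    load_taxon_summary,
    round_as_printed,
)

summary = load_taxon_summary()

print(f"{'taxon':<22}{'avg P450s':>10}{'diversity %':>13}{'in BGCs %':>11}")
for taxon, row in summary.iterrows():
    avg = round_as_printed(
        average_p450s(int(row.n_p450s), int(row.n_species_with_p450s)), 0
    )
    div = round_as_printed(
        diversity_percentage(int(row.n_families), int(row.n_p450s),
                             int(row.n_species_with_p450s)), 2
    )
    bgc = round_as_printed(
        bgc_percentage(int(row.n_p450s_in_bgcs), int(row.n_p450s)), 1
    )
    print(f"{taxon:<22}{avg:>10g}{div:>13g}{bgc:>11g}")

rows = load_published_family_census()
print(f"\npublished family census: {len(rows)} families, "
      f"{sum(r.count for r in rows)} P450s")
top = sorted(rows, key=lambda r: -r.count)[:5]
for r in top:
    pct = round_as_printed(100 * r.count / sum(x.count for x in rows), 2)
    print(f"  CYP{r.family:<6} {r.count:>3} P450s  ({pct}% of the total)")
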