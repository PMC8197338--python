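"""Census aggregation and the comparative diversity statistics.

Given per-protein classification verdicts, this module builds the census
tables (per-family and per-subfamily counts with percentage
contributions) and computes the three comparative statistics used for
cross-taxon P450 surveys:

* average number of P450s  =  P450s / species,
* P450 diversity percentage  =  100 x families / (P450s x species with P450s),
* percentage of P450s in BGCs  =  100 x P450s in BGCs / total P450s.

Published census tables round half away from zero (e.g. 8.009 prints as
8.01 and 22.55 as 23), so ``round_as_printed`` implements that rule rather
than banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .nomenclature import ClassificationResult
from .refdb_io import FamilyCensusRow, write_family_census_tsv

__all__ = [
    "load_taxon_summary",
    "load_published_family_census",
    "CensusTotals",
    "CensusTable",
    "FamilySetComparison",
    "build_census",
    "per_species_family_counts",
    "average_p450s",
    "diversity_percentage",
    "bgc_percentage",
    "compare_family_sets",
    "round_as_printed",
    "write_census_tsv",
    "write_summary_tsv",
]


def _data_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("cypcensus").joinpath("data", name)))


def load_taxon_summary() -> pd.DataFrame:
    """Published per-taxon census inputs (integer counts only).

    Columns: taxon, n_species_analyzed, n_species_with_p450s,
    n_genera_analyzed, n_genera_with_p450s, n_p450s, n_families,
    n_subfamilies, n_p450s_in_bgcs, dominant_family.  Derived statistics
    are never stored; compute them with the formulas in this module.
    """
    return pd.read_csv(_data_path("taxon_p450_summary.tsv"), sep="\t",
                       index_col="taxon")


def load_published_family_census():
    """The published alphaproteobacterial family/subfamily census table."""
    from .refdb_io import read_family_census_tsv

    return read_family_census_tsv(
        _data_path("alphaproteobacteria_family_census.tsv")
    )


@dataclass(frozen=True)
class CensusTotals:
    n_p450s: int
    n_families: int
    n_subfamilies: int
    n_species_analyzed: int
    n_species_with_p450s: int
    n_genera_analyzed: int
    n_genera_with_p450s: int
    n_short: int = 0


@dataclass(frozen=True)
class CensusTable:
    """Family and subfamily counts plus cohort totals.

    ``family_table`` columns: family, count, percentage (of all censused
    P450s); ``subfamily_table`` columns: family, subfamily, count.
    """

    family_table: pd.DataFrame
    subfamily_table: pd.DataFrame
    totals: CensusTotals


def _genus(species: str) -> str:
    return species.split()[0] if species.split() else species


def build_census(
    results: Sequence[ClassificationResult],
    roster: Iterable[str],
) -> CensusTable:
    """Aggregate classification results over a species roster.

    The roster lists every species analysed (including P450-free ones);
    genus is the first whitespace token of the species name.  Short and
    rejected records are excluded from all totals.  A result naming a
    species absent from the roster is an error.
    """
    roster_list = list(dict.fromkeys(roster))
    roster_set = set(roster_list)
    missing = {r.species for r in results} - roster_set
    if missing:
        raise ValueError(f"species not in roster: {sorted(missing)}")

    counted = [r for r in results if r.counted]
    fam_counts: dict[str, int] = {}
    sub_counts: dict[tuple[str, str], int] = {}
    for r in counted:
        name = r.assigned_name
        fam_counts[name.family] = fam_counts.get(name.family, 0) + 1
        key = (name.family, name.subfamily)
        sub_counts[key] = sub_counts.get(key, 0) + 1

    n = len(counted)
    fam_rows = [
        {"family": f, "count": c, "percentage": 100.0 * c / n if n else 0.0}
        for f, c in sorted(fam_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    sub_rows = [
        {"family": f, "subfamily": s, "count": c}
        for (f, s), c in sorted(sub_counts.items())
    ]

    species_with = {r.species for r in counted}
    totals = CensusTotals(
        n_p450s=n,
        n_families=len(fam_counts),
        n_subfamilies=len(sub_counts),
        n_species_analyzed=len(roster_list),
        n_species_with_p450s=len(species_with),
        n_genera_analyzed=len({_genus(s) for s in roster_list}),
        n_genera_with_p450s=len({_genus(s) for s in species_with}),
        n_short=sum(r.status == "short" for r in results),
    )
    return CensusTable(
        family_table=pd.DataFrame(fam_rows, columns=["family", "count", "percentage"]),
        subfamily_table=pd.DataFrame(sub_rows, columns=["family", "subfamily", "count"]),
        totals=totals,
    )


def per_species_family_counts(
    results: Sequence[ClassificationResult],
) -> pd.DataFrame:
    """Species x family table of censused P450 counts (P450-bearing
    species only; observed families only)."""
    counted = [r for r in results if r.counted]
    if not counted:
        return pd.DataFrame()
    tidy = pd.DataFrame(
        {"species": r.species, "family": r.assigned_name.family} for r in counted
    )
    return (
        tidy.groupby(["species", "family"]).size().unstack(fill_value=0).sort_index()
    )


# ---------------------------------------------------------------------------
# Comparative statistics
# ---------------------------------------------------------------------------

def average_p450s(n_p450s: int, n_species: int) -> float:
    """Average P450 complement per species (denominator: species that
    have P450s, in line with published census tables)."""
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    return n_p450s / n_species


def diversity_percentage(n_families: int, n_p450s: int, n_species_with_p450s: int) -> float:
    """100 x families / (P450s x species with P450s).

    Normalises family richness by both repertoire size and cohort size so
    taxa surveyed at different depths can be compared.
    """
    if n_p450s <= 0 or n_species_with_p450s <= 0:
        raise ValueError("denominators must be positive")
    return 100.0 * n_families / (n_p450s * n_species_with_p450s)


def bgc_percentage(n_p450s_in_bgcs: int, n_p450s: int) -> float:
    """100 x P450s inside BGCs / total P450s."""
    if n_p450s <= 0:
        raise ValueError("n_p450s must be positive")
    return 100.0 * n_p450s_in_bgcs / n_p450s


def round_as_printed(x: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (8.009 -> 8.01,
    22.55 -> 23 at zero places)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Cross-taxon family-set comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySetComparison:
    """Venn-style decomposition of per-taxon family sets.

    ``exact_regions`` maps each taxon combination to the families found in
    exactly those taxa (and no others); ``pairwise_intersections`` gives
    plain two-way overlaps; ``universal`` is the families shared by all
    taxa.
    """

    taxa: tuple[str, ...]
    exact_regions: dict[frozenset, tuple[str, ...]]
    pairwise_intersections: dict[tuple[str, str], tuple[str, ...]]
    universal: tuple[str, ...]

    def exact_count(self, *taxa: str) -> int:
        return len(self.exact_regions.get(frozenset(taxa), ()))

    def pairwise_count(self, a: str, b: str) -> int:
        key = tuple(sorted((a, b)))
        return len(self.pairwise_intersections.get(key, ()))


def compare_family_sets(sets: Mapping[str, Iterable[str]]) -> FamilySetComparison:
    """Exact Venn regions and pairwise overlaps of per-taxon family sets."""
    norm = {taxon: {str(f).strip() for f in fams} for taxon, fams in sets.items()}
    taxa = tuple(norm)
    regions: dict[frozenset, tuple[str, ...]] = {}
    all_fams = set().union(*norm.values()) if norm else set()
    for fam in all_fams:
        holder = frozenset(t for t, fams in norm.items() if fam in fams)
        regions.setdefault(holder, ())
    for holder in list(regions):
        fams = sorted(f for f in all_fams
                      if frozenset(t for t in taxa if f in norm[t]) == holder)
        regions[holder] = tuple(fams)
    pairwise_ix = {
        tuple(sorted((a, b))): tuple(sorted(norm[a] & norm[b]))
        for a, b in combinations(taxa, 2)
    }
    universal = tuple(sorted(set.intersection(*norm.values()))) if norm else ()
    return FamilySetComparison(
        taxa=taxa,
        exact_regions=regions,
        pairwise_intersections=pairwise_ix,
        universal=universal,
    )


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def write_census_tsv(table: CensusTable, path: str | Path) -> None:
    """Write the family/subfamily census in the published-table layout."""
    subs_by_family: dict[str, dict[str, int]] = {}
    for row in table.subfamily_table.itertuples(index=False):
        subs_by_family.setdefault(row.family, {})[row.subfamily] = row.count
    rows = [
        FamilyCensusRow(
            family=r.family,
            count=r.count,
            percentage=round_as_printed(r.percentage, 2),
            subfamilies=subs_by_family.get(r.family, {}),
        )
        for r in table.family_table.itertuples(index=False)
    ]
    write_family_census_tsv(rows, path)


def write_summary_tsv(
    table: CensusTable, path: str | Path, n_p450s_in_bgcs: int | None = None
) -> None:
    """Write the cohort summary (totals plus derived statistics)."""
    t = table.totals
    lines = [
        ("Total no of species analyzed", t.n_species_analyzed),
        ("No of species that have P450s", t.n_species_with_p450s),
        ("Total no of genera analyzed", t.n_genera_analyzed),
        ("No of genera that have P450s", t.n_genera_with_p450s),
        ("No of P450s", t.n_p450s),
        ("No of short-P450s (excluded)", t.n_short),
        ("No of families", t.n_families),
        ("No of subfamilies", t.n_subfamilies),
    ]
    if t.n_species_with_p450s and t.n_p450s:
        lines.append((
            "Average no. of P450s",
            round_as_printed(average_p450s(t.n_p450s, t.n_species_with_p450s), 0),
        ))
        lines.append((
            "P450 diversity percentage",
            round_as_printed(
                diversity_percentage(t.n_families, t.n_p450s, t.n_species_with_p450s), 2
            ),
        ))
    if n_p450s_in_bgcs is not None and t.n_p450s:
        lines.append(("No of P450s part of BGCs", n_p450s_in_bgcs))
        lines.append((
            "Percentage of P450s part of BGCs",
            round_as_printed(bgc_percentage(n_p450s_in_bgcs, t.n_p450s), 1),
        ))
    with open(path, "w") as fh:
        fh.write("category\tvalue\n")
        for label, value in lines:
            fh.write(f"{label}\t{value}\n")
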