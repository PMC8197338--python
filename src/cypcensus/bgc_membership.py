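"""Biosynthetic gene cluster (BGC) regions and P450 membership calls.

Genome miners type secondary-metabolite regions with antiSMASH labels
(terpene, hserlactone, bacteriocin, betalactone, NRPS, T1PKS, ...).  A P450
gene counts as *part of* a cluster when its full genomic interval lies
inside the region on the same contig — full containment, not mere overlap,
matching the sense in which a cluster "contains" its genes.  Coordinates
are 1-based and inclusive (GenBank convention); strand is ignored for
membership.

Two plain-text inputs are read: a simplified region TSV (one row per
region) and a gene-coordinate TSV for the classified P450 genes.  An
optional reader extracts regions from antiSMASH GenBank files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BGCRegion",
    "GeneLocus",
    "Membership",
    "BGCSummary",
    "parse_bgc_table",
    "parse_gene_table",
    "write_bgc_table",
    "write_gene_table",
    "read_genbank_regions",
    "p450s_in_bgcs",
    "tally_cluster_types",
    "bgc_summary",
    "write_membership_tsv",
]

_BGC_COLUMNS = [
    "species", "region_id", "cluster_type", "contig", "start", "end",
    "most_similar_known_cluster", "similarity",
]
_GENE_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "is_p450", "cyp_name"]


@dataclass(frozen=True)
class BGCRegion:
    """One secondary-metabolite region; hybrid regions carry several labels."""

    species: str
    region_id: str
    cluster_types: tuple[str, ...]
    contig: str
    start: int
    end: int
    most_similar_known_cluster: str | None = None
    similarity: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.region_id}: start {self.start} > end {self.end}"
            )
        if self.similarity is not None and not 0.0 <= self.similarity <= 100.0:
            raise ValueError(f"{self.region_id}: similarity outside [0, 100]")


@dataclass(frozen=True)
class GeneLocus:
    """A gene interval; ``cyp_name`` is set for classified P450 genes."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    is_p450: bool = False
    cyp_name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class Membership:
    """One P450-inside-BGC call."""

    gene: GeneLocus
    region: BGCRegion

    @property
    def cluster_type(self) -> str:
        return ", ".join(self.region.cluster_types)


def _parse_similarity(raw: str) -> float | None:
    s = str(raw).strip()
    if not s or s in {"-", "nan", "None"}:
        return None
    return float(s.rstrip("%"))


def parse_bgc_table(path: str | Path) -> list[BGCRegion]:
    """Read the simplified region TSV dialect.

    Expected columns: species, region_id, cluster_type, contig, start, end,
    most_similar_known_cluster, similarity.  Hybrid cluster types are
    comma-separated ("hserlactone, t2pks"); similarity accepts "100%" or
    "100".  Unknown columns provoke a warning and are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in _BGC_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown BGC table columns {unknown}")
    missing = [c for c in ("region_id", "cluster_type", "contig", "start", "end")
               if c not in df.columns]
    if missing:
        raise ValueError(f"BGC table missing required columns {missing}")
    regions = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        regions.append(BGCRegion(
            species=d.get("species", ""),
            region_id=d["region_id"],
            cluster_types=tuple(
                t.strip() for t in d["cluster_type"].split(",") if t.strip()
            ),
            contig=d["contig"],
            start=int(d["start"]),
            end=int(d["end"]),
            most_similar_known_cluster=(d.get("most_similar_known_cluster") or None)
            if d.get("most_similar_known_cluster", "") not in {"", "-"} else None,
            similarity=_parse_similarity(d.get("similarity", "")),
        ))
    return regions


def write_bgc_table(regions: Iterable[BGCRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_BGC_COLUMNS) + "\n")
        for r in regions:
            sim = f"{r.similarity:g}%" if r.similarity is not None else "-"
            fh.write("\t".join([
                r.species, r.region_id, ", ".join(r.cluster_types), r.contig,
                str(r.start), str(r.end), r.most_similar_known_cluster or "-", sim,
            ]) + "\n")


def parse_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read the gene-coordinate TSV (one row per gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene_id", "contig", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing required columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        genes.append(GeneLocus(
            gene_id=d["gene_id"],
            contig=d["contig"],
            start=int(d["start"]),
            end=int(d["end"]),
            strand=d.get("strand", "+") or "+",
            is_p450=str(d.get("is_p450", "")).strip().lower() in {"1", "true", "yes"},
            cyp_name=d.get("cyp_name") or None,
        ))
    return genes


def write_gene_table(genes: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write("\t".join([
                g.gene_id, g.contig, str(g.start), str(g.end), g.strand,
                "true" if g.is_p450 else "false", g.cyp_name or "",
            ]) + "\n")


def read_genbank_regions(path: str | Path, species: str = "") -> list[BGCRegion]:
    """Extract region features from an antiSMASH GenBank file.

    Reads ``region`` features (falling back to ``cluster`` for older
    outputs); the ``product`` qualifiers become the cluster type labels.
    Feature coordinates are converted to 1-based inclusive.
    """
    from Bio import SeqIO  # local import: only needed for this reader

    regions: list[BGCRegion] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        n = 0
        for feat in rec.features:
            if feat.type not in {"region", "cluster"}:
                continue
            n += 1
            products = tuple(feat.qualifiers.get("product", ())) or ("unknown",)
            regions.append(BGCRegion(
                species=species,
                region_id=f"{rec.id}.region{n:03d}",
                cluster_types=products,
                contig=rec.id,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
            ))
    return regions


def p450s_in_bgcs(
    genes: Iterable[GeneLocus], regions: Iterable[BGCRegion]
) -> list[Membership]:
    """Call membership: a P450 whose full interval lies inside a region.

    A gene straddling a region boundary is *not* a member.  A gene inside
    several (nested/overlapping) regions yields one record per region.
    """
    region_list = list(regions)
    out: list[Membership] = []
    for g in genes:
        if not g.is_p450:
            continue
        for r in region_list:
            if r.contig == g.contig and r.start <= g.start and g.end <= r.end:
                out.append(Membership(gene=g, region=r))
    return out


def tally_cluster_types(regions: Iterable[BGCRegion]) -> dict[str, int]:
    """Count regions per cluster-type label; hybrids count once per label."""
    counts: dict[str, int] = {}
    for r in regions:
        for label in r.cluster_types:
            counts[label] = counts.get(label, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


@dataclass(frozen=True)
class BGCSummary:
    n_member_p450s: int
    n_contributing_species: int
    per_family_counts: Mapping[str, int]
    percentage_of_p450s: float


def bgc_summary(memberships: Iterable[Membership], n_p450s_total: int) -> BGCSummary:
    """Aggregate membership calls against the census total.

    The percentage is the share of all censused P450s that sit inside
    BGCs, computed with the census formula (see ``census_stats``).
    """
    from .census_stats import bgc_percentage  # avoid a module cycle
    from .refdb_io import parse_cyp_name

    mems = list(memberships)
    distinct_genes = {(m.gene.contig, m.gene.gene_id) for m in mems}
    species = {m.region.species for m in mems}
    fams: dict[str, int] = {}
    for m in mems:
        if m.gene.cyp_name:
            fam = parse_cyp_name(m.gene.cyp_name).family
            fams[fam] = fams.get(fam, 0) + 1
    pct = bgc_percentage(len(distinct_genes), n_p450s_total) if n_p450s_total else 0.0
    return BGCSummary(
        n_member_p450s=len(distinct_genes),
        n_contributing_species=len(species),
        per_family_counts=dict(sorted(fams.items())),
        percentage_of_p450s=pct,
    )


def write_membership_tsv(memberships: Iterable[Membership], path: str | Path) -> None:
    """One row per call: species, P450 name, cluster type, best known cluster."""
    with open(path, "w") as fh:
        fh.write("species\tp450\tgene_id\tregion_id\tcluster_type\t"
                 "most_similar_known_cluster\tsimilarity\n")
        for m in memberships:
            sim = (f"{m.region.similarity:g}%"
                   if m.region.similarity is not None else "-")
            fh.write("\t".join([
                m.region.species, m.gene.cyp_name or "-", m.gene.gene_id,
                m.region.region_id, m.cluster_type,
                m.region.most_similar_known_cluster or "-", sim,
            ]) + "\n")
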