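"""Synthetic proteomes, reference databases and genomes with known truth.

Every downstream stage of the census pipeline (classification, census
statistics, BGC membership, pathway calls) is tested against data whose
correct answer is known by construction:

* reference databases of named P450s built from random background
  sequences carrying the canonical heme-ligand motif;
* proteomes containing mutated copies of those references at controlled
  global identity, plus short fragments and non-P450 decoys;
* genomes with gene coordinates and BGC intervals in which a chosen subset
  of P450 genes is fully contained.

Mutation is substitution-only (no indels), so the realised global-alignment
identity of a mutant equals its target to within 1/L; indel robustness is
exercised separately with small fixed fixtures in the test suite.  All
generators are pure functions of (spec, seed).

The generators emulate census study conditions — species with zero P450s
(the majority of surveyed alphaproteobacterial species lack them), species
with a single P450, and P450-rich species with up to 17 — but they do not
simulate phylogenetically realistic sequence evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bgc_membership import BGCRegion, GeneLocus
from .refdb_io import AMINO_ACIDS, CypName, NamedP450, ReferenceDB, parse_cyp_name

__all__ = [
    "BACKGROUND_FREQUENCIES",
    "HEME_MOTIF_EXAMPLE",
    "SyntheticSpeciesSpec",
    "SyntheticGenomeSpec",
    "random_protein",
    "mutate_to_identity",
    "generate_reference_db",
    "generate_species",
    "generate_genome_with_bgcs",
    "write_species_fasta",
]

#: Fixed background amino-acid frequencies (order matches AMINO_ACIDS).
#: Rounded from large-database protein composition averages; chosen for
#: reproducibility, not organism-specific realism.
BACKGROUND_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "C": 0.0136, "D": 0.0546, "E": 0.0675, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0966,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0534, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}
_FREQ_VECTOR = np.array([BACKGROUND_FREQUENCIES[a] for a in AMINO_ACIDS])
_FREQ_VECTOR = _FREQ_VECTOR / _FREQ_VECTOR.sum()

#: A concrete instance of the P450 heme-ligand motif F-x-x-G-x-x-x-C-x-G,
#: planted in synthetic reference sequences so the motif screen finds them.
HEME_MOTIF_EXAMPLE = "FGAGRHACIG"


def random_protein(length: int, seed: int | np.random.Generator) -> str:
    """An i.i.d. random protein drawn from the background frequencies."""
    if length <= 0:
        raise ValueError(f"protein length must be positive, got {length}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=_FREQ_VECTOR)
    return "".join(AMINO_ACIDS[i] for i in idx)


def mutate_to_identity(template: str, target: float, seed: int | np.random.Generator) -> str:
    """Substitute residues so that global identity to ``template`` is ``target``.

    Exactly ``round((1 - target) * L)`` uniformly chosen positions are
    replaced with a uniformly chosen *different* residue; no indels are
    introduced, so the ungapped identity equals the target to within 1/L.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target identity must be in [0, 1], got {target}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    length = len(template)
    n_sub = int(round((1.0 - target) * length))
    positions = rng.choice(length, size=n_sub, replace=False)
    seq = list(template)
    for pos in positions:
        alternatives = AMINO_ACIDS.replace(seq[pos], "")
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def generate_reference_db(
    names: Sequence[str],
    length: int = 420,
    seed: int = 0,
    motif: str = HEME_MOTIF_EXAMPLE,
) -> ReferenceDB:
    """A reference database of independent random P450s with the heme motif.

    Each name must follow the CYP grammar; sequences are mutually unrelated
    (chance-level identity), so they found distinct families unless their
    names say otherwise.  The motif is planted at a fixed offset from the
    C-terminus, mirroring the real motif's position.
    """
    rng = np.random.default_rng(seed)
    db = ReferenceDB()
    for raw in names:
        name = parse_cyp_name(raw)
        seq = random_protein(length, rng)
        pos = max(0, length - 60)
        seq = seq[:pos] + motif + seq[pos + len(motif):]
        db.add(NamedP450(name=name, sequence=seq))
    return db


@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """Recipe for one synthetic species proteome.

    ``identity_targets`` lists (reference name, target global identity)
    pairs, one per emitted P450; ``n_short`` truncated fragments and
    ``n_decoys`` random non-P450 proteins are appended.  The genus is the
    first whitespace token of ``species_name``.
    """

    species_name: str
    identity_targets: tuple[tuple[str, float], ...] = ()
    n_short: int = 0
    n_decoys: int = 0
    seed: int = 0
    short_length: int = 150
    decoy_length: int = 400

    def __post_init__(self) -> None:
        for ref, t in self.identity_targets:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"identity target for {ref} out of [0, 1]: {t}")

    @property
    def n_p450s(self) -> int:
        return len(self.identity_targets)


def _expected_verdict(ref: CypName, target: float) -> tuple[str, str | None, str | None]:
    """(status, family, subfamily) implied by the >40% / >55% rule."""
    if target > 0.55:
        return "existing_subfamily", ref.family, ref.subfamily
    if target > 0.40:
        return "new_subfamily", ref.family, None
    return "new_family", None, None


def generate_species(
    spec: SyntheticSpeciesSpec, refdb: ReferenceDB
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit (records, truth table) for one synthetic species.

    Records are (id, sequence) pairs in emission order: mutated P450s,
    then short fragments, then decoys.  The truth table records the
    intended classification verdict for every record.
    """
    rng = np.random.default_rng(spec.seed)
    tag = spec.species_name.split()[0] if spec.species_name.split() else "sp"
    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    for i, (ref_raw, target) in enumerate(spec.identity_targets, start=1):
        ref = next((e for e in refdb if e.name.raw.upper() == ref_raw.upper()), None)
        if ref is None:
            raise KeyError(f"reference {ref_raw} not in database")
        seq = mutate_to_identity(ref.sequence, target, rng)
        qid = f"{tag}_p450_{i:03d}"
        status, fam, sub = _expected_verdict(ref.name, target)
        records.append((qid, seq))
        truth_rows.append({
            "query_id": qid, "kind": "p450", "reference": ref.name.raw,
            "target_identity": target, "expected_status": status,
            "expected_family": fam, "expected_subfamily": sub,
        })

    templates = list(refdb) or None
    for i in range(1, spec.n_short + 1):
        if templates:
            tmpl = templates[int(rng.integers(len(templates)))].sequence
            seq = mutate_to_identity(tmpl, 0.8, rng)[: spec.short_length]
        else:
            seq = random_protein(spec.short_length, rng)
        qid = f"{tag}_short_{i:03d}"
        records.append((qid, seq))
        truth_rows.append({
            "query_id": qid, "kind": "short", "reference": None,
            "target_identity": None, "expected_status": "short",
            "expected_family": None, "expected_subfamily": None,
        })

    for i in range(1, spec.n_decoys + 1):
        qid = f"{tag}_decoy_{i:03d}"
        records.append((qid, random_protein(spec.decoy_length, rng)))
        truth_rows.append({
            "query_id": qid, "kind": "decoy", "reference": None,
            "target_identity": None, "expected_status": "new_family",
            "expected_family": None, "expected_subfamily": None,
        })

    columns = ["query_id", "kind", "reference", "target_identity",
               "expected_status", "expected_family", "expected_subfamily"]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return records, truth


def write_species_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Genomes with BGC intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Recipe for a genome layout with planted BGC membership truth.

    Genes are laid end to end (1-based inclusive coordinates, never
    overlapping); each BGC covers a consecutive run of genes with margins.
    ``n_member_p450s`` P450 genes are placed fully inside BGC intervals,
    ``n_nonmember_p450s`` outside them, and, when ``straddle_p450`` is set,
    one extra P450 straddles the last region's boundary (a non-member
    under the full-containment rule).
    """

    species: str = "Synthetica exempli"
    n_genes: int = 10
    n_bgcs: int = 2
    n_member_p450s: int = 3
    n_nonmember_p450s: int = 1
    cluster_types: tuple[str, ...] = (
        "terpene", "hserlactone", "bacteriocin", "betalactone", "NRPS",
    )
    straddle_p450: bool = False
    contig: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_bgcs > 0 and self.n_genes < 2 * self.n_bgcs:
            raise ValueError("need at least two genes per BGC")
        per_bgc = 0 if self.n_bgcs == 0 else -(-self.n_member_p450s // self.n_bgcs)
        if self.n_bgcs and per_bgc > self.n_genes // self.n_bgcs:
            raise ValueError("too many member P450s for the gene count")
        if self.n_bgcs == 0 and self.n_member_p450s:
            raise ValueError("member P450s require at least one BGC")


def generate_genome_with_bgcs(
    spec: SyntheticGenomeSpec, seed: int = 0
) -> tuple[list[GeneLocus], list[BGCRegion], frozenset[str]]:
    """(genes, regions, member truth set) for a synthetic genome.

    The returned truth set contains the gene ids of exactly those P450s
    whose intervals lie fully inside a BGC region.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneLocus] = []
    pos = 1
    coords: list[tuple[int, int]] = []
    for _ in range(spec.n_genes):
        length = int(rng.integers(900, 1500))
        coords.append((pos, pos + length - 1))
        pos += length + int(rng.integers(100, 400))

    # consecutive, disjoint gene runs for the BGCs, spread across the genome
    run_len = 0 if spec.n_bgcs == 0 else max(
        2, -(-spec.n_member_p450s // spec.n_bgcs) + 1
    )
    run_starts: list[int] = []
    if spec.n_bgcs:
        stride = spec.n_genes // spec.n_bgcs
        run_starts = [b * stride for b in range(spec.n_bgcs)]
        run_len = min(run_len, stride)
    bgc_gene_idx: list[list[int]] = [
        list(range(s, s + run_len)) for s in run_starts
    ]
    inside = sorted(i for run in bgc_gene_idx for i in run)
    outside = [i for i in range(spec.n_genes) if i not in inside]

    member_idx = inside[: spec.n_member_p450s]
    nonmember_idx = outside[: spec.n_nonmember_p450s]
    if len(nonmember_idx) < spec.n_nonmember_p450s:
        raise ValueError("not enough genes outside BGCs for non-member P450s")

    p450_idx = set(member_idx) | set(nonmember_idx)
    straddle_gene: int | None = None
    if spec.straddle_p450:
        candidates = [i for i in inside if i not in p450_idx]
        if not candidates:
            raise ValueError("no free in-BGC gene available to straddle")
        straddle_gene = candidates[-1]
        p450_idx.add(straddle_gene)

    cyp_counter = 0
    for i, (start, end) in enumerate(coords):
        is_p450 = i in p450_idx
        cyp_name = None
        if is_p450:
            cyp_counter += 1
            cyp_name = f"CYP9{cyp_counter:03d}A1"  # synthetic provisional names
        genes.append(GeneLocus(
            gene_id=f"gene_{i + 1:03d}",
            contig=spec.contig,
            start=start,
            end=end,
            strand="+" if rng.integers(2) else "-",
            is_p450=is_p450,
            cyp_name=cyp_name,
        ))

    regions: list[BGCRegion] = []
    for b, run in enumerate(bgc_gene_idx):
        start = max(1, coords[run[0]][0] - 50)
        end = coords[run[-1]][1] + 50
        if straddle_gene is not None and straddle_gene in run:
            g = coords[straddle_gene]
            end = (g[0] + g[1]) // 2  # cut through the straddling gene
        regions.append(BGCRegion(
            species=spec.species,
            region_id=f"region_{b + 1:03d}",
            cluster_types=(spec.cluster_types[b % len(spec.cluster_types)],),
            contig=spec.contig,
            start=start,
            end=end,
        ))

    members = frozenset(
        g.gene_id for g in genes if g.is_p450 and any(
            r.contig == g.contig and r.start <= g.start and g.end <= r.end
            for r in regions
        )
    )
    return genes, regions, members
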