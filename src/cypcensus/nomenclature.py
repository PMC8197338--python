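"""Identity-threshold family/subfamily assignment of candidate P450s.

The nomenclature rule: a candidate sharing **>40%** global identity with a
named P450 joins that P450's family, **>55%** identity joins its
subfamily; a candidate at or below 40% identity to every named P450 founds
a new family.  Assignment is best-hit-only — the single highest-identity
reference decides, mirroring manual curation practice — and boundaries are
strict (exactly 40.0% or 55.0% falls to the lower band).

Classification is an incremental greedy clustering: names allocated for
one query (with provisional family numbers / subfamily letters) become
references for the queries that follow in the same run.

Candidates shorter than a length cutoff are labelled ``short`` and kept
out of census totals; published censuses exclude such truncated
"short-P450s" without stating the cutoff, so it is configurable here
(default 300 aa, roughly two-thirds of a typical bacterial P450).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from . import pairwise
from .pairwise import AlignmentParams, GLOBAL_DEFAULTS
from .refdb_io import CypName, NamedP450, ReferenceDB

__all__ = [
    "ClassifierThresholds",
    "ClassificationResult",
    "classify_protein",
    "classify_proteome",
    "screen_candidate",
    "read_proteome_fasta",
    "write_classification_tsv",
    "write_species_summary_tsv",
    "species_summary",
]

Status = Literal["existing_subfamily", "new_subfamily", "new_family", "short", "rejected"]

#: Canonical heme-ligand motif: F-x-x-G-x-x-x-C-x-G (the cysteine is the
#: axial heme ligand).  Fixed positions within a 10-residue window.
_MOTIF_POSITIONS = {0: "F", 3: "G", 7: "C", 9: "G"}
_MOTIF_LEN = 10


@dataclass(frozen=True)
class ClassifierThresholds:
    """Identity bands and the short-sequence cutoff.

    ``strict_inequality`` fixes the boundary semantics: with the default
    True, ">40%" means strictly greater, so exactly 40.0 founds a new
    family.
    """

    family_min: float = 40.0
    subfamily_min: float = 55.0
    short_min_length: int = 300
    strict_inequality: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.family_min < self.subfamily_min < 100.0:
            raise ValueError(
                "need 0 < family_min < subfamily_min < 100, got "
                f"{self.family_min} / {self.subfamily_min}"
            )

    def exceeds(self, identity: float, bound: float) -> bool:
        return identity > bound if self.strict_inequality else identity >= bound


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    species: str
    length: int
    status: Status
    best_hit: str | None = None
    best_identity: float | None = None
    assigned_name: CypName | None = None
    provisional: bool = False
    runner_up: str | None = None
    runner_up_identity: float | None = None

    @property
    def counted(self) -> bool:
        """Whether this record enters census totals."""
        return self.status in ("existing_subfamily", "new_subfamily", "new_family")


def screen_candidate(sequence: str, max_mismatches: int = 1) -> bool:
    """Heuristic heme-ligand motif screen (F-x-x-G-x-x-x-C-x-G, one
    mismatch allowed by default).

    A coarse stand-in for proper domain detection, disabled by default in
    the pipeline, which normally trusts its candidate FASTA.
    """
    seq = sequence.upper()
    for i in range(len(seq) - _MOTIF_LEN + 1):
        mismatches = sum(
            1 for off, res in _MOTIF_POSITIONS.items() if seq[i + off] != res
        )
        if mismatches <= max_mismatches:
            return True
    return False


def _best_hit(
    sequence: str, db: ReferenceDB, params: AlignmentParams
) -> tuple[NamedP450 | None, float, NamedP450 | None, float]:
    """(best entry, identity, best entry of any *other* family, identity)."""
    best: NamedP450 | None = None
    best_id = -1.0
    per_family_best: dict[str, tuple[float, NamedP450]] = {}
    for entry in db:
        r = pairwise.align(sequence, entry.sequence, params)
        ident = pairwise.percent_identity(r)
        if ident > best_id:
            best, best_id = entry, ident
        fam = entry.name.family
        if fam not in per_family_best or ident > per_family_best[fam][0]:
            per_family_best[fam] = (ident, entry)
    runner: NamedP450 | None = None
    runner_id = -1.0
    if best is not None and len(per_family_best) > 1:
        runner_id, runner = max(
            (v for f, v in per_family_best.items() if f != best.name.family),
            key=lambda v: v[0],
        )
    return best, best_id, runner, runner_id


def classify_protein(
    query_id: str,
    sequence: str,
    db: ReferenceDB,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    params: AlignmentParams = GLOBAL_DEFAULTS,
    *,
    species: str = "",
    screen: bool = False,
) -> ClassificationResult:
    """Classify one candidate against the reference database.

    The database is *not* modified; ``classify_proteome`` handles the
    incremental augmentation.  An empty database yields a new family
    unconditionally.
    """
    if not sequence:
        raise ValueError(f"{query_id}: empty sequence")
    sequence = sequence.upper()

    if screen and not screen_candidate(sequence):
        return ClassificationResult(query_id, species, len(sequence), "rejected")
    if len(sequence) < thresholds.short_min_length:
        return ClassificationResult(query_id, species, len(sequence), "short")

    best, best_id, runner, runner_id = _best_hit(sequence, db, params)
    if best is None:
        name = CypName(family=db.next_family_number, subfamily="A", allele=1)
        return ClassificationResult(
            query_id, species, len(sequence), "new_family",
            best_hit=None, best_identity=0.0, assigned_name=name, provisional=True,
        )

    if runner is not None and thresholds.exceeds(runner_id, thresholds.family_min):
        warnings.warn(
            f"{query_id}: best hit {best.name.raw} ({best_id:.1f}%) but family "
            f"{runner.name.family} also above the family threshold "
            f"({runner_id:.1f}%); assigning by best hit"
        )
    else:
        runner, runner_id = None, None  # only report genuine conflicts

    if thresholds.exceeds(best_id, thresholds.subfamily_min):
        fam, sub = best.name.family, best.name.subfamily
        name = CypName(fam, sub, db.next_allele(fam, sub))
        status, provisional = "existing_subfamily", False
    elif thresholds.exceeds(best_id, thresholds.family_min):
        fam = best.name.family
        name = CypName(fam, db.next_subfamily_letter(fam), 1)
        status, provisional = "new_subfamily", True
    else:
        name = CypName(db.next_family_number, "A", 1)
        status, provisional = "new_family", True

    return ClassificationResult(
        query_id, species, len(sequence), status,
        best_hit=best.name.raw, best_identity=best_id,
        assigned_name=name, provisional=provisional,
        runner_up=runner.name.raw if runner else None,
        runner_up_identity=runner_id,
    )


def classify_proteome(
    records: Iterable[tuple[str, str]],
    species: str,
    db: ReferenceDB,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    params: AlignmentParams = GLOBAL_DEFAULTS,
    *,
    screen: bool = False,
) -> list[ClassificationResult]:
    """Classify a proteome's candidates sequentially, in input order.

    Newly allocated names are added to ``db`` as the run proceeds, so
    later queries can match them (pass ``db.copy()`` to keep the original
    database untouched).  Duplicate query ids are an error.
    """
    results: list[ClassificationResult] = []
    seen: set[str] = set()
    for query_id, sequence in records:
        if query_id in seen:
            raise ValueError(f"duplicate query id {query_id!r}")
        seen.add(query_id)
        res = classify_protein(
            query_id, sequence, db, thresholds, params,
            species=species, screen=screen,
        )
        if res.counted:
            db.add(NamedP450(name=res.assigned_name, sequence=sequence.upper()))
        results.append(res)
    return results


def read_proteome_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def write_classification_tsv(
    results: Iterable[ClassificationResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tspecies\tlength\tstatus\tbest_hit\tbest_identity\t"
                 "assigned_name\tprovisional\trunner_up\trunner_up_identity\n")
        for r in results:
            fh.write("\t".join([
                r.query_id, r.species, str(r.length), r.status,
                r.best_hit or "-",
                f"{r.best_identity:.2f}" if r.best_identity is not None else "-",
                r.assigned_name.raw if r.assigned_name else "-",
                "provisional" if r.provisional else "-",
                r.runner_up or "-",
                f"{r.runner_up_identity:.2f}" if r.runner_up_identity is not None else "-",
            ]) + "\n")


def read_classification_tsv(path: str | Path) -> list[ClassificationResult]:
    """Read back a TSV written by ``write_classification_tsv``."""
    from .refdb_io import parse_cyp_name

    results: list[ClassificationResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "query_id":
            raise ValueError(f"unexpected classification header {header!r}")
        for line in fh:
            (qid, species, length, status, best_hit, best_identity,
             assigned, provisional, runner, runner_identity) = line.rstrip("\n").split("\t")
            results.append(ClassificationResult(
                query_id=qid,
                species=species,
                length=int(length),
                status=status,  # type: ignore[arg-type]
                best_hit=None if best_hit == "-" else best_hit,
                best_identity=None if best_identity == "-" else float(best_identity),
                assigned_name=None if assigned == "-" else parse_cyp_name(assigned),
                provisional=provisional == "provisional",
                runner_up=None if runner == "-" else runner,
                runner_up_identity=None if runner_identity == "-" else float(runner_identity),
            ))
    return results


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_records: int
    n_p450s: int
    n_short: int
    n_rejected: int
    n_new_families: int
    p450_free: bool


def species_summary(results: Sequence[ClassificationResult]) -> list[SpeciesSummary]:
    out: list[SpeciesSummary] = []
    for sp in dict.fromkeys(r.species for r in results):
        rs = [r for r in results if r.species == sp]
        n_counted = sum(r.counted for r in rs)
        out.append(SpeciesSummary(
            species=sp,
            n_records=len(rs),
            n_p450s=n_counted,
            n_short=sum(r.status == "short" for r in rs),
            n_rejected=sum(r.status == "rejected" for r in rs),
            n_new_families=sum(r.status == "new_family" for r in rs),
            p450_free=n_counted == 0,
        ))
    return out


def write_species_summary_tsv(
    results: Sequence[ClassificationResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_records\tn_p450s\tn_short\tn_rejected\t"
                 "n_new_families\tp450_free\n")
        for s in species_summary(results):
            fh.write(f"{s.species}\t{s.n_records}\t{s.n_p450s}\t{s.n_short}\t"
                     f"{s.n_rejected}\t{s.n_new_families}\t"
                     f"{'yes' if s.p450_free else 'no'}\n")
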