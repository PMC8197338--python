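"""Cytochrome P450 nomenclature and the named-reference database.

Bacterial P450s are named ``CYP`` + family number + subfamily letter(s) +
allele number, optionally followed by a ``v``-variant suffix, e.g.
``CYP202A1`` or ``CYP127A3v1``.  The family token is numeric, the subfamily
token is one or more uppercase letters (``_`` marks an unassigned
subfamily, which does occur in published census tables), and the allele is
a positive integer.

This module parses and formats those names, holds the reference database
of named P450s used for identity-threshold classification, and reads and
writes the tabular census dialects (family/subfamily census TSV shaped
like the published tables).
"""

from __future__ import annotations

import itertools
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "CypName",
    "CypNameError",
    "NamedP450",
    "ReferenceDB",
    "parse_cyp_name",
    "load_reference_db",
    "write_reference_db",
    "export_alignment_fasta",
    "read_family_census_tsv",
    "write_family_census_tsv",
]

#: The 20 standard amino acids; ``X`` (unknown residue) is additionally
#: accepted in sequences but never scores as a match.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

_NAME_RE = re.compile(
    r"""^CYP
        (?P<family>[0-9]+)
        (?P<subfamily>[A-Z]+|_)
        (?P<allele>[0-9]+)
        (?P<variant>v[0-9]+)?
        $""",
    re.IGNORECASE | re.VERBOSE,
)


class CypNameError(ValueError):
    """Raised when a string does not follow the CYP name grammar."""


@dataclass(frozen=True, order=True)
class CypName:
    """A parsed CYP name.

    ``family`` is kept as a string key: printed family tokens never carry
    leading zeros, and treating them as opaque keys avoids accidental
    renumbering.
    """

    family: str
    subfamily: str
    allele: int
    variant: str | None = None

    def __post_init__(self) -> None:
        if not self.family.isdigit():
            raise CypNameError(f"family token must be numeric, got {self.family!r}")
        if not (self.subfamily == "_" or self.subfamily.isalpha()):
            raise CypNameError(f"bad subfamily token {self.subfamily!r}")
        if self.allele < 1:
            raise CypNameError(f"allele must be a positive integer, got {self.allele}")

    @property
    def raw(self) -> str:
        """The canonical formatted name, e.g. ``CYP202A1``."""
        return f"CYP{self.family}{self.subfamily}{self.allele}{self.variant or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw


def parse_cyp_name(raw: str) -> CypName:
    """Parse ``raw`` (case-insensitive) into its nomenclature components.

    The family is the maximal digit run after the ``CYP`` prefix, the
    subfamily the maximal following letter run (possibly multi-letter, e.g.
    ``JE``; ``_`` when explicitly unassigned), the allele the following
    digit run, optionally followed by a ``v<digits>`` variant.  Anything
    left over is an error.

    >>> parse_cyp_name("CYP101D2")
    CypName(family='101', subfamily='D', allele=2, variant=None)
    """
    s = raw.strip()
    if not s.upper().startswith("CYP"):
        raise CypNameError(f"{raw!r} does not start with 'CYP'")
    m = _NAME_RE.match(s)
    if m is None:
        raise CypNameError(f"{raw!r} does not follow the CYP name grammar "
                           "(CYP<family digits><subfamily letters><allele>[v<digits>])")
    variant = m.group("variant")
    sub = m.group("subfamily")
    return CypName(
        family=m.group("family"),
        subfamily=sub if sub == "_" else sub.upper(),
        allele=int(m.group("allele")),
        variant=variant.lower() if variant else None,
    )


@dataclass(frozen=True)
class NamedP450:
    """A named reference P450 protein sequence."""

    name: CypName
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name.raw}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.name.raw}: invalid residues {sorted(bad)} "
                "(alphabet is the 20 amino acids plus X)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _subfamily_letters() -> Iterator[str]:
    """A, B, ..., Z, AA, AB, ... (Excel-style column order)."""
    for n in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=n):
            yield "".join(combo)


class ReferenceDB:
    """The named-P450 reference set plus new-name allocator state.

    New family numbers are handed out sequentially above the maximum
    observed family number; new subfamily letters within a family follow
    A, B, ..., Z, AA, ... skipping letters already in use.  The authoritative
    nomenclature committee assigns numbers centrally, so every allocation
    made here is provisional (callers flag it as such in their outputs).
    """

    def __init__(self, entries: Iterable[NamedP450] = ()) -> None:
        self._entries: list[NamedP450] = []
        self._by_raw: dict[str, NamedP450] = {}
        self.family_index: dict[str, list[NamedP450]] = {}
        for e in entries:
            self.add(e)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[NamedP450]:
        return iter(self._entries)

    def __contains__(self, raw: str) -> bool:
        return raw.upper() in self._by_raw

    @property
    def entries(self) -> list[NamedP450]:
        return list(self._entries)

    @property
    def families(self) -> set[str]:
        return set(self.family_index)

    def subfamilies(self, family: str) -> set[str]:
        return {e.name.subfamily for e in self.family_index.get(family, [])}

    # -- mutation -----------------------------------------------------------
    def add(self, entry: NamedP450) -> None:
        key = entry.name.raw.upper()
        if key in self._by_raw:
            raise ValueError(f"duplicate P450 name {entry.name.raw}")
        self._entries.append(entry)
        self._by_raw[key] = entry
        self.family_index.setdefault(entry.name.family, []).append(entry)

    def copy(self) -> "ReferenceDB":
        return ReferenceDB(self._entries)

    # -- allocation ---------------------------------------------------------
    @property
    def next_family_number(self) -> str:
        highest = max((int(f) for f in self.family_index), default=0)
        return str(highest + 1)

    def next_subfamily_letter(self, family: str) -> str:
        used = self.subfamilies(family)
        for letters in _subfamily_letters():
            if letters not in used:
                return letters
        raise RuntimeError("unreachable")  # pragma: no cover

    def next_allele(self, family: str, subfamily: str) -> int:
        highest = max(
            (e.name.allele for e in self.family_index.get(family, [])
             if e.name.subfamily == subfamily),
            default=0,
        )
        return highest + 1


def load_reference_db(fasta_path: str | Path) -> ReferenceDB:
    """Load a reference database from FASTA.

    The first whitespace-separated token of each record ID must parse as a
    CYP name; duplicates and unparsable IDs are errors.
    """
    db = ReferenceDB()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        token = rec.id.split("|")[0]
        try:
            name = parse_cyp_name(token)
        except CypNameError as exc:
            raise CypNameError(f"record {rec.id!r}: {exc}") from exc
        db.add(NamedP450(name=name, sequence=str(rec.seq).upper()))
    return db


def write_reference_db(db: ReferenceDB, fasta_path: str | Path) -> None:
    """Write the database back to FASTA (IDs are canonical raw names)."""
    export_alignment_fasta(db.entries, fasta_path)


def export_alignment_fasta(p450s: Iterable[NamedP450], path: str | Path) -> None:
    """Write a multi-FASTA of named P450s for external aligners.

    Record IDs are the raw CYP names, unchanged; sequences are written
    unwrapped so the file round-trips byte-identically through reloading.
    """
    records = [
        SeqRecord(Seq(p.sequence), id=p.name.raw, description="")
        for p in p450s
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Census table dialect (family / count / percentage / subfamily / count),
# mirroring the layout of published P450 census tables: the family columns
# are blank on continuation rows listing further subfamilies.
# ---------------------------------------------------------------------------

@dataclass
class FamilyCensusRow:
    family: str
    count: int
    percentage: float | None
    subfamilies: dict[str, int] = field(default_factory=dict)


def read_family_census_tsv(path: str | Path) -> list[FamilyCensusRow]:
    """Parse a family/subfamily census TSV in the published-table layout."""
    rows: list[FamilyCensusRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["family", "count"]:
            raise ValueError(f"unexpected census header {header!r}")
        current: FamilyCensusRow | None = None
        for lineno, line in enumerate(fh, start=2):
            parts = (line.rstrip("\n").split("\t") + [""] * 5)[:5]
            fam, count, pct, sub, subcount = (p.strip() for p in parts)
            if fam:
                family_token = fam[3:] if fam.upper().startswith("CYP") else fam
                if not family_token.isdigit():
                    raise ValueError(f"line {lineno}: bad family token {fam!r}")
                current = FamilyCensusRow(
                    family=family_token,
                    count=int(count),
                    percentage=float(pct.rstrip("%")) if pct else None,
                )
                rows.append(current)
            if sub:
                if current is None:
                    raise ValueError(f"line {lineno}: subfamily row before any family row")
                current.subfamilies[sub] = int(subcount)
    return rows


def write_family_census_tsv(rows: Iterable[FamilyCensusRow], path: str | Path) -> None:
    """Write census rows in the same published-table layout."""
    with open(path, "w") as fh:
        fh.write("family\tcount\tpercentage\tsubfamily\tsubfamily_count\n")
        for row in rows:
            pct = f"{row.percentage:.2f}%" if row.percentage is not None else ""
            subs = sorted(row.subfamilies.items())
            if not subs:
                fh.write(f"CYP{row.family}\t{row.count}\t{pct}\t\t\n")
                continue
            first = True
            for sub, n in subs:
                if first:
                    fh.write(f"CYP{row.family}\t{row.count}\t{pct}\t{sub}\t{n}\n")
                    first = False
                else:
                    fh.write(f"\t\t\t{sub}\t{n}\n")
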