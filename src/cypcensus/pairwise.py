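"""Pairwise protein alignment with identity / similarity / coverage accounting.

Family and subfamily assignment in the P450 nomenclature, and best-homolog
pathway calls, both hinge on pairwise percent identity.  This module wraps
an affine-gap dynamic-programming aligner (Gotoh, via Biopython's C
implementation) and computes the three statistics the downstream stages
consume:

* **percent identity** — identical residue pairs over alignment columns,
* **percent similarity** ("homology" in census tables) — residue pairs with
  a positive substitution score over alignment columns,
* **coverage** — the fraction of each input's residues inside the aligned
  span.

Column accounting follows BLAST-style semantics: in global mode, terminal
gap columns (overhangs) are excluded from the alignment length, so a clean
fragment still aligns at high identity; in local mode the aligned span is
what the engine reports.  ``X`` is treated as an unknown residue: it scores
at the matrix floor, never counts as identical and never as similar.

Gap costs use the convention that a gap of length *k* costs
``gap_open + (k - 1) * gap_extend``; the defaults (12, 1) are equivalent to
the BLAST protein defaults quoted as "open 11, extend 1".
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal

from Bio import Align
from Bio.Align import substitution_matrices

from .refdb_io import AMINO_ACIDS, _VALID_RESIDUES

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "align",
    "percent_identity",
    "percent_similarity",
    "coverage",
    "substitution_score",
    "dump_pairwise_tsv",
]

ALPHABET = AMINO_ACIDS + "X"


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment mode and scoring parameters.

    ``gap_open`` is the cost of a gap of length 1; extending an existing
    gap by one residue costs ``gap_extend``.
    """

    mode: Literal["global", "local"] = "global"
    matrix: str = "BLOSUM62"
    gap_open: float = 12.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError(f"mode must be 'global' or 'local', got {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


#: Defaults used by the nomenclature classifier (full-length comparison).
GLOBAL_DEFAULTS = AlignmentParams(mode="global")
#: Defaults used by the homolog search (BLAST-like local comparison).
LOCAL_DEFAULTS = AlignmentParams(mode="local")


@lru_cache(maxsize=None)
def _matrix(name: str) -> substitution_matrices.Array:
    """Substitution matrix restricted to the 20 amino acids plus X.

    X is forced to the matrix floor against everything (it matches
    nothing), regardless of the published matrix's X column.
    """
    src = substitution_matrices.load(name)
    floor = float(src.min())
    out = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            if "X" in (a, b):
                out[a, b] = floor
            else:
                out[a, b] = src[a, b]
    return out


def substitution_score(a: str, b: str, matrix: str = "BLOSUM62") -> float:
    """Score of aligning residue ``a`` against residue ``b``."""
    return float(_matrix(matrix)[a, b])


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = _matrix(params.matrix)
    al.open_gap_score = -float(params.gap_open)
    al.extend_gap_score = -float(params.gap_extend)
    al.mode = params.mode
    return al


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise alignment plus its column statistics.

    ``aligned_query``/``aligned_subject`` are the gapped rows over the
    scored span (terminal-gap columns already trimmed in global mode).
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    n_identical: int
    n_similar: int
    alignment_length: int
    query_cover: float
    subject_cover: float


def _check_sequence(label: str, seq: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    s = seq.upper()
    bad = set(s) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"{label}: residues {sorted(bad)} outside the alphabet "
                         f"(20 amino acids + X)")
    return s


def align(
    a: str,
    b: str,
    params: AlignmentParams = GLOBAL_DEFAULTS,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal pairwise alignment of ``a`` (query) against ``b`` (subject).

    The engine's first optimal traceback is used, which is deterministic:
    repeated calls return byte-identical results.
    """
    sa = _check_sequence(query_id, a)
    sb = _check_sequence(subject_id, b)
    try:
        aln = _aligner(params).align(sa, sb)[0]
    except IndexError:
        # local mode with no positively scoring pair: empty alignment
        return AlignmentResult(
            query_id=query_id, subject_id=subject_id,
            aligned_query="", aligned_subject="", score=0.0,
            n_identical=0, n_similar=0, alignment_length=0,
            query_cover=0.0, subject_cover=0.0,
        )
    row_a, row_b = str(aln[0]), str(aln[1])

    lo, hi = 0, len(row_a)
    if params.mode == "global":
        while lo < hi and ("-" in (row_a[lo], row_b[lo])):
            # only trim runs that touch the ends (terminal gaps)
            if _is_terminal_gap(row_a, row_b, lo, from_start=True):
                lo += 1
            else:
                break
        while hi > lo and ("-" in (row_a[hi - 1], row_b[hi - 1])):
            if _is_terminal_gap(row_a, row_b, hi - 1, from_start=False):
                hi -= 1
            else:
                break
    span_a, span_b = row_a[lo:hi], row_b[lo:hi]

    mat = _matrix(params.matrix)
    n_ident = n_sim = 0
    for ca, cb in zip(span_a, span_b):
        if "-" in (ca, cb):
            continue
        if ca == cb and ca != "X":
            n_ident += 1
        if "X" not in (ca, cb) and mat[ca, cb] > 0:
            n_sim += 1
    length = len(span_a)
    q_res = sum(1 for c in span_a if c != "-")
    s_res = sum(1 for c in span_b if c != "-")
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        aligned_query=span_a,
        aligned_subject=span_b,
        score=float(aln.score),
        n_identical=n_ident,
        n_similar=n_sim,
        alignment_length=length,
        query_cover=q_res / len(sa),
        subject_cover=s_res / len(sb),
    )


def _is_terminal_gap(row_a: str, row_b: str, col: int, *, from_start: bool) -> bool:
    """True if the gap at ``col`` belongs to a run touching the alignment end."""
    row = row_a if row_a[col] == "-" else row_b
    cols = range(col, -1, -1) if from_start else range(col, len(row))
    return all(row[c] == "-" for c in cols)


def percent_identity(r: AlignmentResult) -> float:
    """100 x identical columns / alignment length (0 for an empty span)."""
    if r.alignment_length == 0:
        return 0.0
    return 100.0 * r.n_identical / r.alignment_length


def percent_similarity(r: AlignmentResult) -> float:
    """100 x positively-scoring columns / alignment length."""
    if r.alignment_length == 0:
        return 0.0
    return 100.0 * r.n_similar / r.alignment_length


def coverage(r: AlignmentResult) -> tuple[float, float]:
    """(query cover, subject cover) as fractions in [0, 1]."""
    return (r.query_cover, r.subject_cover)


def dump_pairwise_tsv(results: Iterable[AlignmentResult], path: str | Path) -> None:
    """Write one row per alignment: ids, identity, similarity, covers, score."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tpercent_identity\tpercent_similarity\t"
                 "query_cover\tsubject_cover\tscore\n")
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{percent_identity(r):.2f}\t"
                f"{percent_similarity(r):.2f}\t{r.query_cover:.3f}\t"
                f"{r.subject_cover:.3f}\t{r.score:g}\n"
            )
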