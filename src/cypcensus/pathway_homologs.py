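"""Best-homolog search and pathway presence calls.

To ask whether a target organism can run a known pathway (e.g. cholesterol
side-chain beta-oxidation), each reference enzyme from a characterised
source organism is searched against the target proteome by local
alignment.  The best scorer is the candidate homolog; the call is made on
percent identity, percent similarity ("homology") and query coverage.

Distantly related organisms are expected to show low identities, so the
default thresholds are permissive (identity >= 25, similarity >= 35,
coverage >= 50) — consistent with the weakest published calls between
distant bacteria — and calls landing within 2 points of any threshold are
flagged ``ambiguous`` so borderline evidence stays visible.  The pathway
is called present only when every reference enzyme has at least one
present homolog.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from . import pairwise
from .pairwise import AlignmentParams, LOCAL_DEFAULTS

__all__ = [
    "HomologThresholds",
    "HomologCall",
    "PathwayReport",
    "best_homolog",
    "run_pathway_panel",
    "read_panel_fasta",
    "write_pathway_report_tsv",
]


@dataclass(frozen=True)
class HomologThresholds:
    """Acceptance bounds (percent identity / similarity / query coverage)
    and the width of the ambiguous band around each of them."""

    id_min: float = 25.0
    sim_min: float = 35.0
    cov_min: float = 50.0
    ambiguous_margin: float = 2.0


@dataclass(frozen=True)
class HomologCall:
    reference_name: str
    reference_id: str
    target_id: str
    percent_identity: float
    percent_similarity: float
    query_cover: float
    subject_cover: float
    score: float
    verdict: str  # present | absent | ambiguous


@dataclass(frozen=True)
class PathwayReport:
    """Per-enzyme homolog calls plus the overall pathway verdict."""

    calls: dict[str, tuple[HomologCall, ...]]
    n_reference_enzymes: int

    @property
    def n_present(self) -> int:
        return sum(
            any(c.verdict == "present" for c in cs) for cs in self.calls.values()
        )

    @property
    def pathway_present(self) -> bool:
        return self.n_present == self.n_reference_enzymes


def _verdict(identity: float, similarity: float, cover_pct: float,
             t: HomologThresholds) -> str:
    passes = identity >= t.id_min and similarity >= t.sim_min and cover_pct >= t.cov_min
    near = (
        abs(identity - t.id_min) < t.ambiguous_margin
        or abs(similarity - t.sim_min) < t.ambiguous_margin
        or abs(cover_pct - t.cov_min) < t.ambiguous_margin
    )
    if near:
        return "ambiguous"
    return "present" if passes else "absent"


def _call(ref_name: str, ref_id: str, ref_seq: str, target_id: str, target_seq: str,
          params: AlignmentParams, t: HomologThresholds) -> HomologCall:
    r = pairwise.align(ref_seq, target_seq, params,
                       query_id=ref_id, subject_id=target_id)
    ident = pairwise.percent_identity(r)
    sim = pairwise.percent_similarity(r)
    return HomologCall(
        reference_name=ref_name,
        reference_id=ref_id,
        target_id=target_id,
        percent_identity=ident,
        percent_similarity=sim,
        query_cover=r.query_cover,
        subject_cover=r.subject_cover,
        score=r.score,
        verdict=_verdict(ident, sim, 100.0 * r.query_cover, t),
    )


def best_homolog(
    ref_name: str,
    ref_id: str,
    ref_seq: str,
    proteome: Sequence[tuple[str, str]],
    params: AlignmentParams = LOCAL_DEFAULTS,
    thresholds: HomologThresholds = HomologThresholds(),
) -> HomologCall:
    """The best local-alignment hit of one reference enzyme.

    The winner has the highest score; ties break by identity, then by
    proteome record id, so results are stable under record reordering.
    """
    if not proteome:
        raise ValueError("empty proteome")
    calls = [
        _call(ref_name, ref_id, ref_seq, tid, tseq, params, thresholds)
        for tid, tseq in proteome
    ]
    return min(calls, key=lambda c: (-c.score, -c.percent_identity, c.target_id))


def run_pathway_panel(
    panel: Sequence[tuple[str, str, str]],
    proteome: Sequence[tuple[str, str]],
    params: AlignmentParams = LOCAL_DEFAULTS,
    thresholds: HomologThresholds = HomologThresholds(),
) -> PathwayReport:
    """Search every panel enzyme against the proteome.

    ``panel`` holds (gene_name, gene_id, sequence) triples.  For each
    enzyme, every target meeting the acceptance bounds is retained (best
    score first) — a reference may legitimately have two homologs — and
    the best hit is always reported even when it fails the call.
    """
    if not proteome:
        raise ValueError("empty proteome")
    report: dict[str, tuple[HomologCall, ...]] = {}
    for gene_name, gene_id, seq in panel:
        calls = sorted(
            (_call(gene_name, gene_id, seq, tid, tseq, params, thresholds)
             for tid, tseq in proteome),
            key=lambda c: (-c.score, -c.percent_identity, c.target_id),
        )
        kept = [c for c in calls if c.verdict == "present"]
        if not kept:
            kept = [calls[0]]
        report[gene_id] = tuple(kept)
    return PathwayReport(calls=report, n_reference_enzymes=len(panel))


def read_panel_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a reference panel whose headers are ``gene_name|gene_id``."""
    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, gid = rec.id.partition("|")
        panel.append((name, gid or name, str(rec.seq).upper()))
    return panel


def write_pathway_report_tsv(report: PathwayReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reference_gene\treference_id\ttarget_protein\t"
                 "percent_identity\tpercent_similarity\tquery_cover\tverdict\n")
        for gene_id, calls in report.calls.items():
            for c in calls:
                fh.write(
                    f"{c.reference_name}\t{c.reference_id}\t{c.target_id}\t"
                    f"{c.percent_identity:.0f}\t{c.percent_similarity:.0f}\t"
                    f"{100 * c.query_cover:.0f}\t{c.verdict}\n"
                )
        fh.write(f"# enzymes present: {report.n_present}/"
                 f"{report.n_reference_enzymes}; pathway "
                 f"{'present' if report.pathway_present else 'absent'}\n")
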