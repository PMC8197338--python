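# Methods

## The classification model

Bacterial P450 nomenclature groups sequences by pairwise percent
identity to named reference P450s: **>40%** identity to a named P450
places a candidate in that P450's family, **>55%** in its subfamily, and
**≤40%** to every named P450 founds a new family.  `cypcensus` implements
this as a greedy incremental clustering:

1. Each query is globally aligned against every database entry; the best
   hit is the entry with the highest percent identity (ties break by
   database order).
2. The verdict follows the best hit alone — no family-average linkage —
   mirroring how curators assign "the same family as the named homolog".
3. Names allocated during a run (new alleles, subfamily letters, family
   numbers) enter the database immediately and are visible to later
   queries.

Boundary semantics are strict: exactly 40.0% or 55.0% falls to the lower
band, reading ">40%" literally.  This is configurable
(`strict_inequality=False` flips both bounds to ≥).

Because the real nomenclature committee assigns family numbers and
subfamily letters centrally, everything allocated locally is marked
*provisional*.  The allocator is a deterministic local convention: family
numbers continue above the highest number observed, subfamily letters run
A…Z, AA, AB, … skipping letters already used in that family.

**Short sequences.** Census practice excludes truncated candidates from
totals but does not publish a length cutoff.  The default here is 300
residues (roughly two-thirds of a typical ~400–450 aa bacterial P450);
it is a parameter, and flagged records are reported, not dropped.

**Candidate screening.** The pipeline trusts its input candidate FASTA.
An optional heuristic screen looks for the heme-ligand motif
F-x-x-G-x-x-x-C-x-G (one mismatch allowed); it is a coarse predicate,
disabled by default, and is no substitute for domain-level detection.

## Alignment and its statistics

Percent identity drives everything, so its definition matters:

* Engine: affine-gap dynamic programming (Gotoh) over BLOSUM62, gap of
  length *k* costing `12 + (k − 1)·1` — numerically identical to the
  BLAST protein default quoted as "open 11, extend 1".  Global mode for
  classification, local for homolog search.
* Identity denominator: alignment columns, excluding terminal-gap
  columns in global mode.  A clean fragment therefore aligns at high
  identity and is handled by the explicit short-sequence rule rather
  than by accidental identity dilution.
* Similarity ("% homology" in census reports): columns whose residue
  pair scores positively under the matrix.
* Coverage: the fraction of each input's residues inside the aligned
  span.
* `X` scores at the matrix floor and never counts as identical or
  similar; an empty local alignment (nothing scores positively) has
  identity 0 by definition.
* Tie-breaking among co-optimal alignments uses the engine's first
  traceback, which is deterministic: repeated runs are byte-identical.
  Scores are verified in the test suite against an independently written
  pure-Python DP, itself validated against literal enumeration of every
  alignment path at tiny lengths.

Whether published censuses computed identity with BLAST, global
alignment, or over the P450 domain only is not stated anywhere we know
of; global full-length DP is this package's documented choice, and the
synthetic tests place their identity targets away from the 38–42% and
53–57% bands so that reasonable definitional differences cannot flip a
verdict.

## Census statistics

For a cohort the package reports family and subfamily counts, percentage
contributions (`100·count/N`), and three comparative statistics:

| statistic | formula | units |
|---|---|---|
| average P450s | `N_P450 / N_species_with_P450s` | count |
| diversity percentage | `100 · N_families / (N_P450 · N_species_with_P450s)` | % |
| BGC share | `100 · N_P450_in_BGC / N_P450` | % |

Published tables are ambiguous about the average's denominator
("number of species"); the with-P450s reading reproduces the published
alphaproteobacterial value (874/241 → 4) and is used throughout.
Rounding is half away from zero, which reproduces published figures such
as 8.01 (from 8.009) and 23 (from 22.55) where banker's rounding or
truncation would not.  One published figure (the Firmicutes diversity
percentage, 0.008) is not reproducible from its own printed inputs under
any rounding consistent with the rest of the table — the formula gives
0.00859 — and the tests assert the computed value while documenting the
mismatch.

## Presence/absence profiling

Family presence is coded 3 and absence −3 (the convention of the
heat-map viewers used for such censuses; the asymmetric codes render as
saturated red/green).  Rows are P450-bearing species, columns observed
families, so all-absent columns cannot occur.  Both axes are clustered
agglomeratively on Euclidean distances; linkage defaults to average
(the classic Mev default) and is configurable to complete or single.
Tie handling among equal merge distances is scipy's deterministic
behaviour.  Dendrograms serialise to Newick with branch lengths chosen so
root-to-leaf depths equal cophenetic merge heights.

## BGC membership

A P450 is part of a secondary-metabolite region iff its full gene
interval lies inside the region on the same contig — containment, not
overlap, because a cluster *contains* its genes; a boundary-straddling
gene is excluded.  Coordinates are 1-based inclusive (GenBank
convention); strand is ignored.  Hybrid regions ("hserlactone, t2pks")
count once per label in type tallies.  Membership is monotone in region
extent: enlarging a region can only add members.

## Pathway homolog calls

Each reference enzyme is searched against the target proteome by local
alignment; the best scorer wins (ties break by identity, then record id,
so results are stable under proteome reordering).  Default acceptance
thresholds are identity ≥ 25, similarity ≥ 35, query coverage ≥ 50 —
permissive because distantly related organisms are expected to align at
low identity, and consistent with the weakest published accepted calls
between distant bacteria (identity 25 / homology 38).  Calls within 2
points of any threshold are flagged *ambiguous* rather than silently
resolved.  All passing hits are retained per enzyme (an enzyme can have
two genuine homologs); the pathway is present only when every enzyme has
at least one passing call.  Published calls additionally weighed database
annotations; that evidence channel is out of scope here.

## Synthetic data: what it does and does not show

The generators are pure functions of (spec, seed):

* **Reference databases** are independent random sequences (fixed
  background amino-acid frequencies, documented in
  `synthetic_data.BACKGROUND_FREQUENCIES`) with the heme motif planted at
  a fixed offset.  Unrelated references align at chance identity
  (≈15–25% globally with gaps), comfortably below the 40% band.
* **Proteomes** contain substitution-only mutants of references at exact
  target identities (`round((1−t)·L)` positions changed, no indels), so
  the realised global identity is analytically controlled to within 1/L.
  Short fragments (default 150 aa) and random decoys are appended.
* **Genomes** lay genes end to end with random intergenic gaps and place
  BGC regions over consecutive gene runs; membership truth is recorded
  by construction, including an optional boundary-straddling P450.

Default study conditions mirror the surveyed cohort: species with zero
P450s (most surveyed species have none), with a single P450, and up to
17 in one genome; identity targets in tests avoid the 38–42% and 53–57%
bands where a ±1 residue difference could legitimately flip a verdict.

What passing these tests does *not* show: robustness to indel-rich
divergence (mutation is substitution-only; a small fixed-indel fixture
exercises terminal-gap handling separately), to phylogenetically
correlated references, or to domain-fusion proteins where full-length
identity and domain identity diverge.  Problem sizes are kept at desk
scale — reference databases of ~6 entries, cohorts of hundreds of
queries, 420-residue proteins — which exercises every code path while
keeping the full suite under a minute of alignment time.

## Numerical and degenerate-input choices

* Identity/similarity percentages of an empty alignment span are 0.
* An empty reference database sends every query to a new family.
* An empty proteome yields an empty result list and a "P450-free"
  species summary.
* A single-row or single-column presence matrix keeps identity ordering
  and gets no dendrogram.
* `round_as_printed` uses decimal arithmetic on the repr of the float,
  avoiding binary-representation surprises at the half boundary.
* Duplicate query ids, duplicate reference names, reversed genomic
  coordinates and out-of-range similarities all raise immediately.

## Known limitations

* Provisional family numbers are a local convention; they will not match
  numbers later assigned by the nomenclature committee.
* Best-hit assignment order-sensitivity: within threshold-adjacent bands
  the greedy clustering can depend on input order (the tests bound this
  away from the bands).
* The BGC reader consumes region annotations; it does not detect
  clusters, and known-cluster similarity is taken as given.
* Eukaryotic-style CYP names with letter-bearing family tokens are out
  of scope.
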