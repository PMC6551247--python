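# Methods

This note documents the models, parameter choices, and numerical
conventions behind `peptig`, and what the synthetic benchmark does and
does not establish.

## Index and graph model

**Multi-string BWT.** Each block of reads is indexed with one sentinel
per read. Sentinels sort below every residue and ties between sentinels
break by read index, so construction is deterministic and the first
*n* BWT rows are the sentinel suffixes in read order (used for
inversion). Suffix sorting uses Python's comparison sort on
(suffix, read-index) keys — O(n log n · L) with short-read L — which is
the right trade-off for a single-threaded reference implementation; the
interface would admit induced sorting without any API change. `X`
(ambiguous residue) is kept in the indexed text but defined to match
nothing as a pattern character, so it can never seed or extend a match
against itself.

**Overlap detection.** One incremental backward search per (read,
block) enumerates all suffixes of the read right-to-left; interval rows
whose suffix-array offset is 0 are prefix matches, i.e. suffix–prefix
overlaps. Only the maximal overlap per ordered pair is kept (length ≥
*l*, default 10 aa). Containment (a read inside another at any offset)
is only tested against the read's own block; this keeps per-block work
independent, at the cost of cross-block artifacts that the graph
cleanup removes. With fixed-length reads — the regime the shredder
produces — every containment is an exact duplicate, for which the
rectification below is exact. Exact duplicates resolve with the lower
read index as container.

**Cleanup.** Transitive edges are reduced *canonically*: all reducible
edges are marked against the original edge set before any removal, so
the reduced graph is independent of iteration order and, importantly,
of how reads were partitioned into blocks. Bubble removal extends each
branching node up to `bubble_depth` nodes (default 10) in both
directions and deletes one of two parallel branches **only when their
spelled sequences are identical**; a single substitution keeps both
branches, which is what preserves polymorphism from low-abundance
genomes. Of two identical branches, the one with fewer member reads
loses; ties go against the shorter interior span and then against the
larger minimum read index, so a duplicated or contained read loses to
its container. A losing branch is removed outright only when its
interior's outside edges are mirrored by the winner — always true for
the cross-block duplicate artifacts this step exists for, and a
structural guarantee that no unique sequence can be disconnected. Tip
trimming removes a two-node dead end only when its spelling is
contained in a through-path of at least three nodes via the same
connector; orphan two-node components are kept. Both passes iterate to
a fixed point and are idempotent there.

**Unitigs.** Maximal unbranched paths collapse into unitigs; member
reads (including contained reads, resolved through containment chains)
are recorded with their offsets. Condensed edges carry the read-level
overlap length at the junction, so any condensed walk spells exactly
the sequence of the underlying read path.

## Search model

Seeding uses exact 6-mers by default. A reduced-alphabet mapping can be
supplied to the seed index (both indexed windows and lookups are mapped)
for more sensitive seeding; scores are always computed on raw residues.
Ungapped extension runs along the seed diagonal with best-prefix
bookkeeping and an X-drop cut-off (X = 20 BLOSUM62 units; `None` scans
the whole diagonal and is exact). Anchors below 25 (default) are
dropped; the best anchor per unitig is kept and anchors are ordered by
descending score with deterministic tie-breaks.

Candidate paths grow from each anchor by DFS in both directions. The
anchor's position inside the query splits the length budget: the
N-side extension targets `query_start × (1 + slack)` added residues and
the C-side `(query_length − query_end) × (1 + slack)` (slack default
0.2), so the assembled path is centered where the anchor sits on the
query. Unitigs claimed by earlier candidate paths block extension, and
any anchor whose unitig is visited during a DFS is dropped — higher-
scoring anchors therefore have priority in recruiting their neighborhood,
and each graph region is traversed once. Branch combinations are capped
at 64 paths per anchor, explored in descending next-unitig anchor-score
order then unitig id, so output is byte-deterministic.

Alignment is a banded local Smith–Waterman with affine gaps (open 11,
extend 1: a gap of length g costs 11 + g, the conventional BLOSUM62
pairing). The band is `max(40, ⌈0.2·|query|⌉)` diagonals either side of
the anchor diagonal re-expressed in path coordinates; at full band the
scores equal an unrestricted DP (property-tested against biopython's
`PairwiseAligner`). E-values use the Karlin–Altschul form with gapped
constants λ = 0.267, K = 0.041 — comparator-calibrated defaults,
exposed as configuration rather than fixed truth. Contigs passing the
E-value cutoff (default 10⁻³) are emitted sorted by E-value.

## Recruitment

Reads map onto contigs by exact 6-mer seeding and banded verification
(band 5 — the generator produces no indels, and sequencing indels in
peptide space are rare; gapped verification still tolerates small
shifts). Identity is matches over alignment columns. Thresholds:
identity ≥ 0.9 over ≥ 0.8 of the read length, and at least 60% of the
read must lie inside the contig's query-aligned interval — candidate
paths are built to match the query length and can carry flanking
non-homologous sequence that must not recruit reads. Conflicts across
queries resolve to the contig with the most significant E-value, then
deterministically by query id, contig id, and position.

The direct-search baseline (`direct_seed_search`) applies the same
seeding, alignment, and E-value acceptance to each read against the
queries themselves; its recall deficit against contig-mediated
recruitment measures exactly the reads that carry no shared 6-mer with
the query but overlap reads that do.

## Synthetic communities

The generator works directly in peptide space: random background
proteomes at SwissProt-like residue frequencies, homolog copies of each
query planted by BLOSUM62-biased substitution to a target identity
(substitution count is `round((1−identity)·L)`, so realized identity is
within rounding of the target; an identity that rounds to zero
substitutions is rejected), and fixed-length reads (default 33 aa ≈ 100
bp of coding sequence) drawn uniformly at the target coverage (default
10X) with per-residue substitution errors (default 1%). Two copies per
query are planted in distinct genomes by default, mutated
independently, emulating a divergent community where the query is ~75%
identical to its nearest relatives. Reads are labeled homolog /
boundary / non-homolog against the planted intervals; boundary reads
(straddling an endpoint) are excluded from both truth sets when
scoring. All outputs are pure functions of parameters and seed.

What the generator does **not** emulate: nucleotide-level simulation
and gene calling (frame errors, truncated peptides), indel sequencing
errors, chimeras, uneven coverage, and real phylogenetic divergence
(substitutions here are i.i.d. BLOSUM62-biased, not tree-structured).
Passing tests therefore demonstrate algorithmic correctness and the
qualitative sensitivity ordering, not field performance on real
metagenomes.

## Problem sizes

Test and acceptance runs use desk-scale communities — 2–6 genomes of
400–1200 residues, 1–2 queries of 150 residues, about 500–2200 reads —
chosen so each full-pipeline run completes in seconds while still
exercising duplicates, containments, bubbles, tips, branch points, and
divergent anchoring. Oracle comparisons (all-pairs overlap scan,
full-matrix DP) run at sizes where the quadratic oracles are exact and
fast.

## Known limitations

* Single-threaded; block partitioning bounds memory but construction is
  not parallelized.
* E-value calibration is configurable but not derived from the search
  statistics of this implementation; absolute E-values should be read
  comparatively.
* Bubble removal deletes whole duplicated branches only under the
  mirrored-edge guard; pathological graphs where identical spellings
  arise from genuinely different loci may retain redundant paths
  (safe, but less compact).
* The tip rule measures the three-node through-path on the uncollapsed
  read graph.
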