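"""Recruit the original peptide reads onto assembled homolog contigs.

Contig-mediated recruitment is what turns the assembler into a homolog
search tool: a read need not share any seed with the query itself -- it
only has to map onto a contig that the graph traversal assembled. Mapping
uses exact k-mer seeds against the contig set followed by banded gapped
verification, mirroring the search stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .alphabet import AMBIGUOUS
from .fm_index import PeptideRead
from .homology_search import (
    DEFAULT_SEED_K,
    HomologContig,
    banded_smith_waterman,
    expand_edit_string,
)

__all__ = ["RecruitedRead", "recruit", "direct_seed_search"]

DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_SPAN = 0.8
DEFAULT_MAP_BAND = 5
#: Fraction of the read that must fall inside the contig's query-aligned
#: (homolog) interval: candidate paths are built to match the query length
#: and may carry non-homologous flanks that should not recruit reads.
DEFAULT_INTERVAL_OVERLAP = 0.6


@dataclass(frozen=True)
class RecruitedRead:
    """A read mapped onto a homolog contig."""

    read_id: str
    contig_id: int
    contig_pos: int
    identity: float
    assigned_query: str
    assigned_evalue: float


def _alignment_stats(edit: str) -> Tuple[int, int]:
    """(matches, alignment columns) from an RLE edit string."""
    matches = cols = 0
    for count, op in expand_edit_string(edit):
        cols += count
        if op == "=":
            matches += count
    return matches, cols


def recruit(
    contigs: Sequence[HomologContig],
    reads: Sequence[PeptideRead],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_span: float = DEFAULT_MIN_SPAN,
    k: int = DEFAULT_SEED_K,
    band: int = DEFAULT_MAP_BAND,
    interval_overlap: float = DEFAULT_INTERVAL_OVERLAP,
) -> List[RecruitedRead]:
    """Map every read against every contig via seeded banded alignment.

    A read is recruited to its best-identity placement among those meeting
    the identity and span thresholds and lying (by at least
    ``interval_overlap`` of the read length) inside the contig's
    query-aligned interval; conflicts between contigs of different queries
    resolve to the contig with the most significant E-value, then the
    smaller query id, then contig id and position, so output is
    deterministic. Each read is assigned at most once.
    """
    if not contigs:
        return []
    # k-mer index over contig sequences
    index: Dict[str, List[Tuple[int, int]]] = {}
    for ci, contig in enumerate(contigs):
        seq = contig.sequence
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if AMBIGUOUS in window:
                continue
            index.setdefault(window, []).append((ci, i))

    recruited: List[RecruitedRead] = []
    for read in reads:
        seq = read.sequence
        candidates: set[Tuple[int, int]] = set()  # (contig idx, diagonal)
        for q in range(len(seq) - k + 1):
            window = seq[q : q + k]
            if AMBIGUOUS in window:
                continue
            for ci, pos in index.get(window, []):
                candidates.add((ci, q - pos))
        best: Optional[Tuple[tuple, RecruitedRead]] = None
        for ci, diag in sorted(candidates):
            contig = contigs[ci]
            aln = banded_smith_waterman(seq, contig.sequence, band, diag_center=diag)
            if aln.score <= 0:
                continue
            matches, cols = _alignment_stats(aln.edit_string)
            if cols == 0:
                continue
            identity = matches / cols
            span = aln.query_interval[1] - aln.query_interval[0]
            if identity < min_identity or span < min_span * len(seq):
                continue
            hs, he = contig.alignment.path_interval
            ps, pe = aln.path_interval
            inside = max(0, min(pe, he) - max(ps, hs))
            if inside < interval_overlap * len(seq):
                continue
            rec = RecruitedRead(
                read_id=read.read_id,
                contig_id=contig.contig_id,
                contig_pos=aln.path_interval[0],
                identity=identity,
                assigned_query=contig.query_id,
                assigned_evalue=contig.evalue,
            )
            key = (-identity, contig.evalue, contig.query_id, contig.contig_id, rec.contig_pos)
            if best is None or key < best[0]:
                best = (key, rec)
        if best is not None:
            recruited.append(best[1])
    return recruited


def direct_seed_search(
    queries: Dict[str, str],
    reads: Sequence[PeptideRead],
    database_residues: int,
    k: int = DEFAULT_SEED_K,
    evalue_cutoff: float = 1e-3,
    band: int = DEFAULT_MAP_BAND,
) -> List[RecruitedRead]:
    """Per-read seeded search directly against the queries (the baseline).

    A read can only be found if it shares an exact k-mer with a query --
    the limitation contig-mediated recruitment overcomes, since a read
    with no shared seed can still map onto an assembled contig whose
    other member reads carried the seeds. Hits are scored by banded local
    alignment and accepted on a Karlin-Altschul E-value, so precision is
    comparable to the contig route; each read is assigned to its
    best-E-value query.
    """
    from .homology_search import evalue_of

    index: Dict[str, List[Tuple[str, int]]] = {}
    for qid in sorted(queries):
        seq = queries[qid]
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if AMBIGUOUS not in window:
                index.setdefault(window, []).append((qid, i))
    found: List[RecruitedRead] = []
    for read in reads:
        seq = read.sequence
        candidates: set[Tuple[str, int]] = set()
        for q in range(len(seq) - k + 1):
            window = seq[q : q + k]
            for qid, pos in index.get(window, []):
                candidates.add((qid, q - pos))
        best: Optional[Tuple[tuple, RecruitedRead]] = None
        for qid, diag in sorted(candidates):
            aln = banded_smith_waterman(seq, queries[qid], band, diag_center=diag)
            if aln.score <= 0:
                continue
            ev = evalue_of(aln.score, len(seq), database_residues)
            if ev > evalue_cutoff:
                continue
            matches, cols = _alignment_stats(aln.edit_string)
            rec = RecruitedRead(read.read_id, -1, aln.path_interval[0], matches / cols, qid, ev)
            key = (ev, qid, aln.path_interval[0])
            if best is None or key < best[0]:
                best = (key, rec)
        if best is not None:
            found.append(best[1])
    return found
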