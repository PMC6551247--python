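"""Seeded homolog search over the unitig graph.

The search follows a filter-traverse-align design: exact k-mer seeds
between the query protein and the unitig sequences are extended into
ungapped anchors under an X-drop rule; anchors are ranked by score;
depth-first traversal of the condensed graph grows each surviving anchor
into candidate paths whose spelled length matches the query length; and a
banded Smith-Waterman with affine gaps scores each candidate path, with
Karlin-Altschul E-values attached. Traversal and alignment never
interleave, so the graph and the dynamic-programming matrices are touched
in separate phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .alphabet import AMBIGUOUS, blosum62, score_ungapped
from .string_graph import UnitigGraph

__all__ = [
    "SeedMatch",
    "Anchor",
    "CandidatePath",
    "AlignmentResult",
    "HomologContig",
    "SeedIndex",
    "index_seeds",
    "ungapped_extend",
    "select_anchors",
    "generate_candidate_paths",
    "banded_smith_waterman",
    "evalue_of",
    "assemble_homologs",
]

DEFAULT_SEED_K = 6
DEFAULT_ANCHOR_THRESHOLD = 25
DEFAULT_XDROP = 20
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_LAMBDA = 0.267
DEFAULT_K_PARAM = 0.041
DEFAULT_PATH_SLACK = 0.2
DEFAULT_MAX_PATHS_PER_ANCHOR = 64


@dataclass(frozen=True)
class SeedMatch:
    """Exact k-mer shared by the query and a unitig."""

    query_pos: int
    unitig_id: int
    unitig_pos: int
    k: int


@dataclass(frozen=True)
class Anchor:
    """Maximal ungapped diagonal segment containing a seed, above threshold."""

    unitig_id: int
    ungapped_score: int
    query_interval: Tuple[int, int]
    unitig_interval: Tuple[int, int]

    @property
    def diagonal(self) -> int:
        return self.query_interval[0] - self.unitig_interval[0]


@dataclass
class CandidatePath:
    """An ordered unitig walk containing >= 1 anchor, spelled into a sequence."""

    unitigs: List[int]
    sequence: str
    source_anchor: Anchor


@dataclass
class AlignmentResult:
    """Local alignment with run-length edit string over '=', 'X', 'I', 'D'.

    'I' consumes the query only (insertion relative to the path), 'D'
    consumes the path only.
    """

    score: int
    query_interval: Tuple[int, int]
    path_interval: Tuple[int, int]
    edit_string: str
    evalue: float = math.inf


@dataclass
class HomologContig:
    """A candidate path accepted by gapped alignment against the query."""

    contig_id: int
    query_id: str
    unitigs: List[int]
    sequence: str
    alignment: AlignmentResult

    @property
    def evalue(self) -> float:
        return self.alignment.evalue

    @property
    def score(self) -> int:
        return self.alignment.score


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


class SeedIndex:
    """k-mer -> [(unitig_id, position)] over all unitig sequences.

    Windows containing ``X`` are never indexed. An optional alphabet
    reduction (a residue -> group-letter mapping) can be applied to both
    the indexed windows and lookups, trading seeding specificity for
    sensitivity; the default is the exact 20-letter alphabet.
    """

    def __init__(self, k: int = DEFAULT_SEED_K, alphabet_map: Optional[Dict[str, str]] = None):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.alphabet_map = alphabet_map
        self._index: Dict[str, List[Tuple[int, int]]] = {}

    def _reduce(self, s: str) -> str:
        if self.alphabet_map is None:
            return s
        return "".join(self.alphabet_map.get(c, c) for c in s)

    def add(self, unitig_id: int, sequence: str) -> None:
        k = self.k
        for i in range(len(sequence) - k + 1):
            window = sequence[i : i + k]
            if AMBIGUOUS in window:
                continue
            self._index.setdefault(self._reduce(window), []).append((unitig_id, i))

    def lookup(self, kmer: str) -> List[Tuple[int, int]]:
        if AMBIGUOUS in kmer:
            return []
        return self._index.get(self._reduce(kmer), [])

    def seeds_for(self, query: str) -> List[SeedMatch]:
        out = []
        for q in range(len(query) - self.k + 1):
            kmer = query[q : q + self.k]
            for uid, pos in self.lookup(kmer):
                out.append(SeedMatch(q, uid, pos, self.k))
        return out


def index_seeds(
    unitig_graph: UnitigGraph,
    k: int = DEFAULT_SEED_K,
    alphabet_map: Optional[Dict[str, str]] = None,
) -> SeedIndex:
    """Index every length-k window of every unitig sequence."""
    idx = SeedIndex(k=k, alphabet_map=alphabet_map)
    for u in unitig_graph.unitigs:
        idx.add(u.unitig_id, u.sequence)
    return idx


# ---------------------------------------------------------------------------
# Ungapped anchors
# ---------------------------------------------------------------------------


def ungapped_extend(
    query: str,
    unitig_seq: str,
    seed: SeedMatch,
    threshold: int = DEFAULT_ANCHOR_THRESHOLD,
    xdrop: Optional[int] = DEFAULT_XDROP,
) -> Optional[Anchor]:
    """Extend a seed along its diagonal into the best ungapped segment.

    Both directions are scanned with running best-prefix bookkeeping; a
    direction stops early once the running sum falls ``xdrop`` below its
    best (``xdrop=None`` scans the whole diagonal). Returns the
    maximal-scoring segment containing the seed, or ``None`` below
    ``threshold``.
    """
    q0, u0, k = seed.query_pos, seed.unitig_pos, seed.k
    # Under a reduced seeding alphabet the raw k-mers may differ; the
    # anchor score is always computed on the raw residues.
    core = score_ungapped(query[q0 : q0 + k], unitig_seq[u0 : u0 + k])

    def extend(direction: int) -> Tuple[int, int]:
        best, run, steps, best_steps = 0, 0, 0, 0
        if direction > 0:
            qi, ui = q0 + k, u0 + k
        else:
            qi, ui = q0 - 1, u0 - 1
        while 0 <= qi < len(query) and 0 <= ui < len(unitig_seq):
            a, b = query[qi], unitig_seq[ui]
            s = -4 if (a == AMBIGUOUS or b == AMBIGUOUS) else blosum62(a, b)
            run += s
            steps += 1
            if run > best:
                best, best_steps = run, steps
            elif xdrop is not None and run < best - xdrop:
                break
            qi += direction
            ui += direction
        return best, best_steps

    right_gain, right_len = extend(+1)
    left_gain, left_len = extend(-1)
    score = core + right_gain + left_gain
    if score < threshold:
        return None
    qs, qe = q0 - left_len, q0 + k + right_len
    us, ue = u0 - left_len, u0 + k + right_len
    return Anchor(seed.unitig_id, score, (qs, qe), (us, ue))


def select_anchors(anchors: Sequence[Anchor], threshold: int = DEFAULT_ANCHOR_THRESHOLD) -> List[Anchor]:
    """Filter by threshold, keep the best anchor per unitig, sort by score.

    Ordering is strictly non-increasing in score; ties break on
    (unitig_id, query start) so the result is deterministic.
    """
    best_per_unitig: Dict[int, Anchor] = {}
    for a in anchors:
        if a.ungapped_score < threshold:
            continue
        cur = best_per_unitig.get(a.unitig_id)
        if (
            cur is None
            or a.ungapped_score > cur.ungapped_score
            or (a.ungapped_score == cur.ungapped_score and a.query_interval < cur.query_interval)
        ):
            best_per_unitig[a.unitig_id] = a
    return sorted(
        best_per_unitig.values(),
        key=lambda a: (-a.ungapped_score, a.unitig_id, a.query_interval[0]),
    )


# ---------------------------------------------------------------------------
# Candidate-path generation
# ---------------------------------------------------------------------------


def generate_candidate_paths(
    unitig_graph: UnitigGraph,
    anchors: Sequence[Anchor],
    query_length: int,
    slack: float = DEFAULT_PATH_SLACK,
    max_paths_per_anchor: int = DEFAULT_MAX_PATHS_PER_ANCHOR,
    anchor_scores: Optional[Dict[int, int]] = None,
) -> List[CandidatePath]:
    """Depth-first candidate-path generation with redundancy suppression.

    Anchors are consumed in the given (descending-score) order. From each
    anchor's unitig, DFS extends toward the N- and C-terminus until the
    added spelled length covers the query flanks (times ``1 + slack``).
    Unitigs already claimed by an earlier candidate path block extension,
    and any anchor whose unitig was visited during a DFS is dropped from
    the pending list, so each graph region is traversed once, with the
    best-scoring anchors given priority.
    """
    if anchor_scores is None:
        anchor_scores = {a.unitig_id: a.ungapped_score for a in anchors}
    claimed: set[int] = set()
    consumed: set[int] = set()
    paths: List[CandidatePath] = []

    def neighbor_order(candidates: Sequence[int]) -> List[int]:
        return sorted(candidates, key=lambda u: (-anchor_scores.get(u, 0), u))

    for anchor in anchors:
        uid = anchor.unitig_id
        if uid in consumed or uid in claimed:
            consumed.add(uid)
            continue
        visited_this_dfs: set[int] = {uid}
        left_budget = anchor.query_interval[0] * (1 + slack)
        right_budget = (query_length - anchor.query_interval[1]) * (1 + slack)

        def walks(direction: str, budget: float) -> List[List[int]]:
            """Maximal simple walks from the anchor in one direction."""
            results: List[List[int]] = []
            nbrs = unitig_graph.inn if direction == "left" else unitig_graph.out

            def added_len(walk: List[int]) -> int:
                total = 0
                for i in range(1, len(walk)):
                    if direction == "right":
                        olen = unitig_graph.out[walk[i - 1]][walk[i]]
                    else:
                        olen = unitig_graph.inn[walk[i - 1]][walk[i]]
                    total += len(unitig_graph.sequence_of(walk[i])) - olen
                return total

            def dfs(walk: List[int]) -> None:
                if len(results) >= max_paths_per_anchor:
                    return
                if added_len(walk) >= budget:
                    results.append(list(walk))
                    return
                extensions = [
                    n
                    for n in neighbor_order(list(nbrs[walk[-1]]))
                    if n not in claimed and n not in walk
                ]
                for n in extensions:
                    visited_this_dfs.add(n)
                if not extensions:
                    results.append(list(walk))
                    return
                for n in extensions:
                    dfs(walk + [n])

            dfs([uid])
            return results

        lefts = walks("left", left_budget)
        rights = walks("right", right_budget)
        for lw in lefts:
            for rw in rights:
                walk = list(reversed(lw))[:-1] + rw  # lw runs anchor -> N-terminus
                if len(set(walk)) != len(walk):
                    continue
                if any(u in claimed for u in walk if u != uid):
                    continue
                seq = unitig_graph.spell_path(walk)
                paths.append(CandidatePath(walk, seq, anchor))
        consumed.add(uid)
        for u in visited_this_dfs:
            consumed.add(u)
        for p in paths:
            claimed.update(p.unitigs)
    return paths


# ---------------------------------------------------------------------------
# Banded Smith-Waterman with affine gaps
# ---------------------------------------------------------------------------


def banded_smith_waterman(
    query: str,
    path_sequence: str,
    band_width: int,
    diag_center: int = 0,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Best local alignment restricted to a diagonal band.

    Cells (i, j) with ``|(i - j) - diag_center| > band_width`` are never
    filled (i indexes the query, j the path sequence, both 1-based in the
    DP). Affine gaps: a gap of length g costs ``gap_open + g * gap_extend``.
    At ``band_width >= len(query) + len(path_sequence)`` this equals the
    unrestricted Smith-Waterman.
    """
    if not query or not path_sequence:
        raise ValueError("sequences must be non-empty")
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    m, n = len(query), len(path_sequence)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in path (consumes query)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (consumes path)
    ptr: Dict[Tuple[int, int], Tuple[str, Tuple[int, int]]] = {}
    best, best_cell = 0, (0, 0)
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        lo = max(1, i - diag_center - band_width)
        hi = min(n, i - diag_center + band_width)
        for j in range(lo, hi + 1):
            diag_in = abs((i - 1) - (j - 1) - diag_center) <= band_width
            e = max(H[i - 1][j] - open_cost, E[i - 1][j] - gap_extend)
            f = max(H[i][j - 1] - open_cost, F[i][j - 1] - gap_extend)
            E[i][j] = e
            F[i][j] = f
            sub = blosum62(query[i - 1], path_sequence[j - 1])
            d = (H[i - 1][j - 1] + sub) if diag_in else NEG
            h = max(0, d, e, f)
            H[i][j] = h
            if h == 0:
                continue
            if h == d:
                op = "=" if query[i - 1] == path_sequence[j - 1] else "X"
                ptr[(i, j)] = (op, (i - 1, j - 1))
            elif h == e:
                ptr[(i, j)] = ("I", (i - 1, j))
            else:
                ptr[(i, j)] = ("D", (i, j - 1))
            if h > best:
                best, best_cell = h, (i, j)
    if best == 0:
        return AlignmentResult(0, (0, 0), (0, 0), "")
    # Traceback through H; gap runs are recovered by following E/F chains.
    ops: List[str] = []
    i, j = best_cell
    while (i, j) in ptr and H[i][j] > 0:
        op, (pi, pj) = ptr[(i, j)]
        if op in "=X":
            ops.append(op)
            i, j = pi, pj
        elif op == "I":
            # walk the E chain up
            while True:
                ops.append("I")
                came_from_h = H[i - 1][j] - open_cost >= E[i - 1][j] - gap_extend
                i -= 1
                if came_from_h:
                    break
        else:
            while True:
                ops.append("D")
                came_from_h = H[i][j - 1] - open_cost >= F[i][j - 1] - gap_extend
                j -= 1
                if came_from_h:
                    break
    ops.reverse()
    edit = _rle(ops)
    return AlignmentResult(best, (i, best_cell[0]), (j, best_cell[1]), edit)


def _rle(ops: Sequence[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def expand_edit_string(edit: str) -> List[Tuple[int, str]]:
    """Parse an RLE edit string into (count, op) pairs."""
    out = []
    num = ""
    for c in edit:
        if c.isdigit():
            num += c
        else:
            out.append((int(num), c))
            num = ""
    return out


def evalue_of(
    score: float,
    query_length: int,
    database_residues: int,
    lam: float = DEFAULT_LAMBDA,
    k_param: float = DEFAULT_K_PARAM,
) -> float:
    """Karlin-Altschul expectation: ``E = K * m * n * exp(-lambda * S)``."""
    if query_length < 1 or database_residues < 1:
        raise ValueError("lengths must be >= 1")
    if score < 0:
        raise ValueError("score must be >= 0")
    return k_param * query_length * database_residues * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# End-to-end search
# ---------------------------------------------------------------------------


def default_band_width(query_length: int) -> int:
    return max(40, math.ceil(0.2 * query_length))


def assemble_homologs(
    query_id: str,
    query: str,
    unitig_graph: UnitigGraph,
    seed_index: SeedIndex,
    database_residues: int,
    evalue_cutoff: float = 1e-3,
    anchor_threshold: int = DEFAULT_ANCHOR_THRESHOLD,
    xdrop: Optional[int] = DEFAULT_XDROP,
    slack: float = DEFAULT_PATH_SLACK,
    max_paths_per_anchor: int = DEFAULT_MAX_PATHS_PER_ANCHOR,
    band_width: Optional[int] = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    lam: float = DEFAULT_LAMBDA,
    k_param: float = DEFAULT_K_PARAM,
) -> List[HomologContig]:
    """Full search: seeds -> anchors -> candidate paths -> banded alignment.

    Emits one contig per candidate path whose E-value passes the cutoff,
    sorted by (E-value, path). No hits yield an empty list.
    """
    if band_width is None:
        band_width = default_band_width(len(query))
    # One extension per (unitig, diagonal): further seeds on the same
    # diagonal produce the same maximal segment.
    anchors: List[Anchor] = []
    seen_diag: set[Tuple[int, int]] = set()
    for seed in seed_index.seeds_for(query):
        key = (seed.unitig_id, seed.query_pos - seed.unitig_pos)
        if key in seen_diag:
            continue
        seen_diag.add(key)
        a = ungapped_extend(
            query,
            unitig_graph.sequence_of(seed.unitig_id),
            seed,
            threshold=anchor_threshold,
            xdrop=xdrop,
        )
        if a is not None:
            anchors.append(a)
    ordered = select_anchors(anchors, threshold=anchor_threshold)
    candidates = generate_candidate_paths(
        unitig_graph,
        ordered,
        len(query),
        slack=slack,
        max_paths_per_anchor=max_paths_per_anchor,
    )
    contigs: List[HomologContig] = []
    for cand in candidates:
        anchor = cand.source_anchor
        # Anchor diagonal re-expressed in path coordinates.
        offset = _unitig_offset_in_path(unitig_graph, cand.unitigs, anchor.unitig_id)
        diag = anchor.query_interval[0] - (offset + anchor.unitig_interval[0])
        aln = banded_smith_waterman(
            query,
            cand.sequence,
            band_width,
            diag_center=diag,
            gap_open=gap_open,
            gap_extend=gap_extend,
        )
        if aln.score <= 0:
            continue
        aln.evalue = evalue_of(aln.score, len(query), database_residues, lam=lam, k_param=k_param)
        if aln.evalue <= evalue_cutoff:
            contigs.append(HomologContig(0, query_id, cand.unitigs, cand.sequence, aln))
    contigs.sort(key=lambda c: (c.evalue, c.unitigs))
    for i, c in enumerate(contigs):
        c.contig_id = i
    return contigs


def _unitig_offset_in_path(graph: UnitigGraph, walk: Sequence[int], uid: int) -> int:
    """Spelled-sequence offset at which ``uid`` starts within the walk."""
    offset = 0
    for a, b in zip(walk, walk[1:]):
        if a == uid:
            return offset
        # spelled offset of b = offset(a) + len(a) - overlap(a, b)
        offset += len(graph.sequence_of(a)) - graph.out[a][b]
    return offset
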