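"""String-graph construction from blockwise FM-index overlap detection.

Reads are nodes; directed edges are maximal suffix-prefix overlaps (read
N-terminal to C-terminal). Contained reads are excluded from the graph and
recorded for recruitment accounting. Because containment is only detected
within a block, cross-block containment artifacts (duplicate reads living
in different blocks) survive as parallel paths or dead ends; they are
rectified downstream by bubble removal and tip trimming, which delete a
branch only when its spelled sequence is redundant. This keeps the graph
SNP-aware: parallel paths whose sequences differ anywhere are both kept.

After cleanup, maximal unbranched paths are collapsed into unitigs whose
spelled sequences are guaranteed substrings of any assembly of the reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .fm_index import BwtBlock, FmInterval, all_sequences

__all__ = [
    "Overlap",
    "Containment",
    "StringGraph",
    "Unitig",
    "UnitigGraph",
    "find_overlaps",
    "build_graph",
    "transitive_reduction",
    "remove_bubbles",
    "trim_tips",
    "collapse_unitigs",
    "build_unitig_graph",
]

DEFAULT_MIN_OVERLAP = 10
DEFAULT_BUBBLE_DEPTH = 10


@dataclass(frozen=True)
class Overlap:
    """Maximal suffix(source)/prefix(target) match of ``length`` residues."""

    source: int
    target: int
    length: int


@dataclass(frozen=True)
class Containment:
    """``contained`` occurs as a substring of ``container`` at ``offset``."""

    contained: int
    container: int
    offset: int


class StringGraph:
    """Directed overlap graph over non-contained reads.

    Edge ``s -> t`` carries the overlap length; its label (the part of the
    target's sequence beyond the overlap) is derived on demand, so spelling
    a path always reconstructs every member read verbatim.
    """

    def __init__(self, sequences: Sequence[str]):
        self.sequences = list(sequences)
        self.nodes: Set[int] = set()
        self.out: Dict[int, Dict[int, int]] = {}  # s -> {t: overlap length}
        self.inn: Dict[int, Dict[int, int]] = {}  # t -> {s: overlap length}
        self.containments: List[Containment] = []

    # -- mutation ----------------------------------------------------------

    def add_node(self, n: int) -> None:
        if n not in self.nodes:
            self.nodes.add(n)
            self.out.setdefault(n, {})
            self.inn.setdefault(n, {})

    def add_edge(self, s: int, t: int, length: int) -> None:
        if s == t:
            raise ValueError("self-loops are not allowed")
        src, tgt = self.sequences[s], self.sequences[t]
        if src[len(src) - length :] != tgt[:length]:
            raise ValueError(
                f"inconsistent overlap: suffix of read {s} != prefix of read {t} "
                f"at length {length}"
            )
        self.add_node(s)
        self.add_node(t)
        self.out[s][t] = length
        self.inn[t][s] = length

    def remove_edge(self, s: int, t: int) -> None:
        self.out[s].pop(t, None)
        self.inn[t].pop(s, None)

    def remove_node(self, n: int) -> None:
        for t in list(self.out.get(n, ())):
            self.remove_edge(n, t)
        for s in list(self.inn.get(n, ())):
            self.remove_edge(s, n)
        self.nodes.discard(n)
        self.out.pop(n, None)
        self.inn.pop(n, None)

    # -- inspection --------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return sum(len(d) for d in self.out.values())

    def edge_label(self, s: int, t: int) -> str:
        """Target suffix appended when walking ``s -> t``."""
        return self.sequences[t][self.out[s][t] :]

    def spell(self, path: Sequence[int]) -> str:
        """Sequence spelled by a node path (reconstructs every member read)."""
        if not path:
            return ""
        seq = self.sequences[path[0]]
        for a, b in zip(path, path[1:]):
            seq += self.edge_label(a, b)
        return seq

    def copy(self) -> "StringGraph":
        g = StringGraph(self.sequences)
        g.nodes = set(self.nodes)
        g.out = {n: dict(d) for n, d in self.out.items()}
        g.inn = {n: dict(d) for n, d in self.inn.items()}
        g.containments = list(self.containments)
        return g


# ---------------------------------------------------------------------------
# Overlap and containment detection
# ---------------------------------------------------------------------------


def find_overlaps(
    blocks: Sequence[BwtBlock], l: int = DEFAULT_MIN_OVERLAP
) -> Tuple[List[Overlap], List[Containment]]:
    """Detect maximal suffix-prefix overlaps across blocks.

    For every read, all blocks are queried by one incremental backward
    search over the read's suffixes (right to left); rows whose suffix
    starts at offset 0 of a longer read are prefix matches, i.e. overlaps.
    For a given ordered pair only the maximal overlap length is kept.

    Containments (a read occurring inside another read at any offset) are
    detected only against the read's *own* block; missed cross-block
    containments surface as redundant parallel paths and are rectified by
    graph cleanup. Exact duplicates resolve with the lower read index as
    container.
    """
    if l < 1:
        raise ValueError("minimum overlap l must be >= 1")
    seqs = all_sequences(blocks)
    if l > max((len(s) for s in seqs), default=0):
        warnings.warn("minimum overlap exceeds every read length; no overlaps possible")
        return [], []

    block_of: Dict[int, int] = {}
    for b, block in enumerate(blocks):
        for idx in block.read_indices:
            block_of[idx] = b

    best: Dict[Tuple[int, int], int] = {}
    containments: Dict[int, Containment] = {}

    for r, seq in enumerate(seqs):
        own_block = block_of[r]
        for b, block in enumerate(blocks):
            interval = block.full_interval()
            for j in range(len(seq) - 1, -1, -1):
                interval = block.extend_left(interval, seq[j])
                if interval.empty:
                    break
                olen = len(seq) - j
                full = olen == len(seq)
                if olen < l and not full:
                    continue
                for row in range(interval.lower, interval.upper):
                    lr, off = int(block.sa[row, 0]), int(block.sa[row, 1])
                    t = block.read_indices[lr]
                    if t == r:
                        continue
                    tlen = len(seqs[t])
                    if full and b == own_block:
                        # Same-block containment channel (any offset).
                        if tlen > olen or (tlen == olen and t < r):
                            prev = containments.get(r)
                            if prev is None:
                                containments[r] = Containment(r, t, off)
                            continue
                    if off != 0 or olen < l:
                        continue
                    if tlen > olen:
                        key = (r, t)
                        if best.get(key, 0) < olen:
                            best[key] = olen
    overlaps = [Overlap(s, t, ln) for (s, t), ln in sorted(best.items())]
    return overlaps, sorted(containments.values(), key=lambda c: c.contained)


def build_graph(
    overlaps: Iterable[Overlap],
    containments: Iterable[Containment],
    sequences: Sequence[str],
) -> StringGraph:
    """Assemble the string graph, excluding contained reads from the nodes."""
    g = StringGraph(sequences)
    contained = {c.contained for c in containments}
    g.containments = sorted(containments, key=lambda c: c.contained)
    for n in range(len(sequences)):
        if n not in contained:
            g.add_node(n)
    for ov in overlaps:
        if ov.source in contained or ov.target in contained:
            continue
        if ov.source == ov.target:
            continue
        g.add_edge(ov.source, ov.target, ov.length)  # validates sequences agree
    return g


def transitive_reduction(graph: StringGraph) -> StringGraph:
    """Remove transitive edges (``v->w`` implied by ``v->u->w`` spelling the same).

    All reducible edges are marked against the *original* edge set before
    any removal, so the result is canonical (independent of iteration
    order and of how reads were partitioned into blocks). The closest
    successor of a node is never reducible, so connectivity survives.
    """
    g = graph
    removable: List[Tuple[int, int]] = []
    for v in sorted(g.nodes):
        targets = g.out[v]
        if len(targets) < 2:
            continue
        for w, len_vw in targets.items():
            for u, len_vu in targets.items():
                if u == w:
                    continue
                len_uw = g.out[u].get(w)
                if len_uw is None:
                    continue
                # v->u->w spells the same string as v->w iff the label
                # lengths agree (labels are suffixes of the same target).
                lab_w = len(g.sequences[w]) - len_vw
                lab_u = len(g.sequences[u]) - len_vu
                lab_uw = len(g.sequences[w]) - len_uw
                if lab_u + lab_uw == lab_w:
                    removable.append((v, w))
                    break
    for v, w in removable:
        g.remove_edge(v, w)
    return g


# ---------------------------------------------------------------------------
# Graph cleanup: bubbles and tips
# ---------------------------------------------------------------------------


def _paths_from(
    graph: StringGraph, v: int, depth: int, max_paths: int = 400
) -> List[List[int]]:
    """All simple directed paths from ``v`` with at most ``depth`` nodes."""
    out: List[List[int]] = []
    stack: List[List[int]] = [[v]]
    while stack and len(out) < max_paths:
        path = stack.pop()
        out.append(path)
        if len(path) >= depth:
            continue
        for t in sorted(graph.out.get(path[-1], ()), reverse=True):
            if t not in path:
                stack.append(path + [t])
    return out


def _branch_deletable(
    graph: StringGraph, lose_interior: Sequence[int], win_interior: Sequence[int]
) -> bool:
    """Is it safe to delete the losing branch's interior nodes outright?

    Safe when every edge touching a losing interior node from outside the
    bubble is mirrored by the winning branch (the cross-block duplicate /
    containment situation this cleanup exists for), or when the interior
    has no outside edges at all.
    """
    lose_set = set(lose_interior)
    win_set = set(win_interior)
    if len(lose_interior) == 1 and len(win_interior) == 1:
        n_l, n_w = lose_interior[0], win_interior[0]
        for p in graph.inn[n_l]:
            if p not in lose_set and p not in graph.inn[n_w] and p != n_w:
                return False
        for q in graph.out[n_l]:
            if q not in lose_set and q not in graph.out[n_w] and q != n_w:
                return False
        return True
    for n in lose_interior:
        for p in graph.inn[n]:
            if p not in lose_set and n != lose_interior[0]:
                return False
        for q in graph.out[n]:
            if q not in lose_set and n != lose_interior[-1]:
                return False
    return True


def remove_bubbles(graph: StringGraph, depth: int = DEFAULT_BUBBLE_DEPTH) -> StringGraph:
    """Pop redundant bubbles: parallel v-u paths with *identical* spellings.

    Parallel paths whose spelled sequences differ anywhere (for instance a
    single substitution from a low-abundance genome) are both retained, so
    polymorphism survives cleanup. Of two identical branches, the one with
    fewer interior reads loses; ties go against the branch with the shorter
    interior span, then against the larger minimum read index -- so a
    contained or duplicated read loses to its container. The losing branch
    is removed only when structurally safe (its interior's outside edges
    are mirrored by the winner).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    changed = True
    while changed:
        changed = False
        for v in sorted(graph.nodes):
            if v not in graph.nodes:
                continue
            if len(graph.out.get(v, ())) < 2:
                continue  # a bubble must branch at its opening node
            paths = _paths_from(graph, v, depth + 1)
            by_end: Dict[int, List[List[int]]] = {}
            for p in paths:
                if len(p) >= 2:
                    by_end.setdefault(p[-1], []).append(p)
            removed_here = False
            for u in sorted(by_end):
                group = by_end[u]
                if len(group) < 2:
                    continue
                for i in range(len(group)):
                    for j in range(i + 1, len(group)):
                        p1, p2 = group[i], group[j]
                        if set(p1[1:-1]) & set(p2[1:-1]):
                            continue  # share interior nodes: not a clean bubble
                        s1, s2 = graph.spell(p1), graph.spell(p2)
                        if s1 != s2:
                            continue
                        lose, win = _choose_loser(graph, p1, p2)
                        li, wi = lose[1:-1], win[1:-1]
                        if not li:
                            graph.remove_edge(lose[0], lose[-1])
                            changed = removed_here = True
                        elif _branch_deletable(graph, li, wi):
                            for n in li:
                                graph.remove_node(n)
                            changed = removed_here = True
                        if removed_here:
                            break
                    if removed_here:
                        break
                if removed_here:
                    break
            # After a removal the enumerated paths for v are stale; move on
            # to the next node and rely on the outer fixed-point loop.
    return graph


def _choose_loser(
    graph: StringGraph, p1: Sequence[int], p2: Sequence[int]
) -> Tuple[List[int], List[int]]:
    """Return (losing path, winning path) for an identical-spelling bubble."""

    def key(p: Sequence[int]) -> tuple:
        interior = p[1:-1]
        span = sum(len(graph.sequences[n]) for n in interior)
        min_idx = min(interior) if interior else -1
        # fewer member reads loses; shorter span loses; larger min index
        # loses (keep the lower-index read, the container convention).
        return (len(interior), span, -min_idx)

    return (list(p1), list(p2)) if key(p1) <= key(p2) else (list(p2), list(p1))


def trim_tips(graph: StringGraph, depth: int = DEFAULT_BUBBLE_DEPTH) -> StringGraph:
    """Remove redundant dead-end branches ("tips").

    A tip is a degree-1 node ``t`` forming a two-node path with its
    connector ``c``; it is removed iff ``c`` lies on an alternative path of
    at least three nodes whose spelled sequence contains the tip path's
    spelling. Orphan two-node components (no longer path through the
    connector) are always retained.
    """
    changed = True
    while changed:
        changed = False
        for t in sorted(graph.nodes):
            if t not in graph.nodes:
                continue
            outd = len(graph.out[t])
            ind = len(graph.inn[t])
            if outd + ind != 1:
                continue
            if outd == 0:  # terminating tip: c -> t
                c = next(iter(graph.inn[t]))
                tip_seq = graph.spell([c, t])
                alt = _alt_paths_through(graph, c, exclude=t, depth=depth, forward=True)
            else:  # beginning tip: t -> c
                c = next(iter(graph.out[t]))
                tip_seq = graph.spell([t, c])
                alt = _alt_paths_through(graph, c, exclude=t, depth=depth, forward=False)
            for path in alt:
                if len(path) >= 3 and tip_seq in graph.spell(path):
                    graph.remove_node(t)
                    changed = True
                    break
    return graph


def _alt_paths_through(
    graph: StringGraph, c: int, exclude: int, depth: int, forward: bool
) -> List[List[int]]:
    """Simple paths through connector ``c`` avoiding ``exclude``.

    For a terminating tip the comparison paths start at ``c`` and run
    forward; for a beginning tip they end at ``c`` (built backward and
    reversed). One extra predecessor/successor of ``c`` is prepended /
    appended where available so the 3-node rule counts the through-path.
    """
    paths: List[List[int]] = []
    if forward:
        for p in _paths_from(graph, c, depth):
            if exclude in p:
                continue
            preds = [x for x in sorted(graph.inn[c]) if x != exclude and x not in p]
            if preds:
                paths.extend([x] + p for x in preds)
            paths.append(p)
    else:
        rev = _reverse_view(graph)
        for p in _paths_from(rev, c, depth):
            if exclude in p:
                continue
            fwd = list(reversed(p))
            succs = [x for x in sorted(graph.out[c]) if x != exclude and x not in fwd]
            if succs:
                paths.extend(fwd + [x] for x in succs)
            paths.append(fwd)
    return paths


def _reverse_view(graph: StringGraph) -> StringGraph:
    g = StringGraph(graph.sequences)
    g.nodes = set(graph.nodes)
    g.out = {n: dict(graph.inn[n]) for n in graph.nodes}
    g.inn = {n: dict(graph.out[n]) for n in graph.nodes}
    return g


# ---------------------------------------------------------------------------
# Unitig collapsing
# ---------------------------------------------------------------------------


@dataclass
class Unitig:
    """A maximal unbranched path collapsed to one sequence.

    ``members`` are (global read index, offset in unitig) placements for
    the path's own reads and any reads contained in them.
    """

    unitig_id: int
    sequence: str
    members: List[Tuple[int, int]]
    path: List[int] = field(default_factory=list)


class UnitigGraph:
    """Condensed graph: unitigs as nodes, read-graph junction edges as links."""

    def __init__(self, unitigs: List[Unitig], edges: List[Tuple[int, int, int]]):
        self.unitigs = unitigs
        self.out: Dict[int, Dict[int, int]] = {u.unitig_id: {} for u in unitigs}
        self.inn: Dict[int, Dict[int, int]] = {u.unitig_id: {} for u in unitigs}
        for a, b, olen in edges:
            self.out[a][b] = olen
            self.inn[b][a] = olen

    @classmethod
    def from_sequences(
        cls, sequences: Dict[int, str], edges: List[Tuple[int, int, int]]
    ) -> "UnitigGraph":
        """Build directly from unitig sequences; used by tests and toy graphs."""
        unitigs = [
            Unitig(uid, seq, members=[], path=[]) for uid, seq in sorted(sequences.items())
        ]
        return cls(unitigs, edges)

    def __getitem__(self, uid: int) -> Unitig:
        return self._by_id[uid]

    @property
    def _by_id(self) -> Dict[int, Unitig]:
        return {u.unitig_id: u for u in self.unitigs}

    def sequence_of(self, uid: int) -> str:
        return self._by_id[uid].sequence

    def spell_path(self, walk: Sequence[int]) -> str:
        """Concatenate unitig spellings along a condensed-graph walk."""
        if not walk:
            return ""
        seq = self.sequence_of(walk[0])
        for a, b in zip(walk, walk[1:]):
            olen = self.out[a][b]
            seq += self.sequence_of(b)[olen:]
        return seq

    def edges(self) -> List[Tuple[int, int, int]]:
        return [(a, b, olen) for a, d in sorted(self.out.items()) for b, olen in sorted(d.items())]


def collapse_unitigs(graph: StringGraph) -> UnitigGraph:
    """Collapse maximal unbranched paths of the cleaned graph into unitigs."""
    g = graph

    def internal(u: int, v: int) -> bool:
        return len(g.out[u]) == 1 and len(g.inn[v]) == 1

    starts = []
    for n in sorted(g.nodes):
        preds = g.inn[n]
        if len(preds) != 1:
            starts.append(n)
        else:
            p = next(iter(preds))
            if not internal(p, n):
                starts.append(n)
    assigned: Set[int] = set()
    chains: List[List[int]] = []
    for s in starts:
        chain = [s]
        assigned.add(s)
        cur = s
        while len(g.out[cur]) == 1:
            nxt = next(iter(g.out[cur]))
            if not internal(cur, nxt) or nxt in assigned:
                break
            chain.append(nxt)
            assigned.add(nxt)
            cur = nxt
        chains.append(chain)
    # Pure cycles have no start node; break each at its minimum node.
    for n in sorted(g.nodes - assigned):
        if n in assigned:
            continue
        chain = [n]
        assigned.add(n)
        cur = n
        while True:
            nxt = next(iter(g.out[cur]))
            if nxt in assigned:
                break
            chain.append(nxt)
            assigned.add(nxt)
            cur = nxt
        chains.append(chain)

    # Containment placements: resolve (possibly chained) containers first.
    placement: Dict[int, Tuple[int, int]] = {}  # read -> (container read, offset)
    for c in g.containments:
        placement[c.contained] = (c.container, c.offset)

    def resolve(read: int) -> Tuple[int, int]:
        offset = 0
        seen = set()
        while read in placement and read not in seen:
            seen.add(read)
            parent, off = placement[read]
            offset += off
            read = parent
        return read, offset

    node_pos: Dict[int, Tuple[int, int]] = {}  # read node -> (unitig id, offset)
    unitigs: List[Unitig] = []
    for uid, chain in enumerate(chains):
        seq = g.spell(chain)
        members: List[Tuple[int, int]] = []
        off = 0
        for i, n in enumerate(chain):
            members.append((n, off))
            node_pos[n] = (uid, off)
            if i + 1 < len(chain):
                off += len(g.sequences[n]) - g.out[n][chain[i + 1]]
        unitigs.append(Unitig(uid, seq, members, path=list(chain)))
    # Attach contained reads onto their container's unitig placement.
    for c in g.containments:
        root, extra = resolve(c.contained)
        if root in node_pos:
            uid, off = node_pos[root]
            unitigs[uid].members.append((c.contained, off + extra))
    for u in unitigs:
        u.members.sort(key=lambda m: (m[1], m[0]))

    edges: List[Tuple[int, int, int]] = []
    chain_of = {chain[0]: uid for uid, chain in enumerate(chains)}
    for uid, chain in enumerate(chains):
        last = chain[-1]
        for t, olen in sorted(g.out[last].items()):
            edges.append((uid, chain_of[t], olen))
    return UnitigGraph(unitigs, edges)


def build_unitig_graph(
    blocks: Sequence[BwtBlock],
    l: int = DEFAULT_MIN_OVERLAP,
    bubble_depth: int = DEFAULT_BUBBLE_DEPTH,
    reduce_transitive: bool = True,
) -> UnitigGraph:
    """Full graph stage: overlaps -> graph -> cleanup -> unitigs."""
    overlaps, containments = find_overlaps(blocks, l=l)
    graph = build_graph(overlaps, containments, all_sequences(blocks))
    if reduce_transitive:
        transitive_reduction(graph)
    remove_bubbles(graph, depth=bubble_depth)
    trim_tips(graph, depth=bubble_depth)
    return collapse_unitigs(graph)
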