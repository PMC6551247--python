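"""Blockwise multi-string BWT / FM-index over a peptide read set.

The read database is partitioned into blocks (in input order); each block
gets its own multi-string Burrows-Wheeler transform with one sentinel per
read, supporting backward search (pattern counting) and locate (occurrence
positions). Blockwise construction bounds the memory footprint of indexing:
only one block's suffix array needs to exist at a time, and downstream
overlap detection queries each block independently.

Conventions
-----------
* One sentinel per read, lexicographically smaller than every residue;
  ties between sentinels are broken by read index, so construction is
  fully deterministic.
* Suffix sorting is delegated to Python's sort on (suffix, read index)
  keys -- O(n log n * L) with short-read L, which is the right trade-off
  at the scales this reference implementation targets.
* ``X`` (ambiguous residue) is kept in the indexed text but is defined to
  match nothing as a pattern character: any pattern containing ``X``
  returns the empty interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .alphabet import AMBIGUOUS, SENTINEL, validate_sequence

__all__ = [
    "PeptideRead",
    "ReadOrigin",
    "FmInterval",
    "BwtBlock",
    "build_blocks",
    "backward_search",
    "locate",
]


@dataclass(frozen=True)
class ReadOrigin:
    """Provenance of a synthetic read: genome id and 0-based half-open interval."""

    genome_id: str
    start: int
    end: int


@dataclass(frozen=True)
class PeptideRead:
    """An amino-acid read; the atomic unit of the database."""

    read_id: str
    sequence: str
    origin: Optional[ReadOrigin] = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, name=f"read {self.read_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FmInterval:
    """Half-open range of BWT rows; ``width`` = number of pattern occurrences."""

    lower: int
    upper: int

    @property
    def width(self) -> int:
        return self.upper - self.lower

    @property
    def empty(self) -> bool:
        return self.upper <= self.lower


class BwtBlock:
    """Multi-string BWT + FM-index over one partition of the read set.

    Parameters
    ----------
    block_id:
        Ordinal of this block in the partition.
    read_indices:
        Global indices (into the full database) of the member reads.
    sequences:
        The member read sequences, in the same order.
    """

    def __init__(self, block_id: int, read_indices: Sequence[int], sequences: Sequence[str]):
        if len(read_indices) != len(sequences):
            raise ValueError("read_indices and sequences must be parallel")
        if not sequences:
            raise ValueError("a BWT block needs at least one read")
        self.block_id = int(block_id)
        self.read_indices = list(map(int, read_indices))
        self.sequences = list(sequences)
        self._build()

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        seqs = self.sequences
        # Suffixes: (local read r, offset p) for p in 0..len, each implicitly
        # terminated by read r's own sentinel. Sorting by (suffix string, r)
        # realises "distinct sentinels ordered by read index".
        entries = [
            (seqs[r][p:], r, p)
            for r in range(len(seqs))
            for p in range(len(seqs[r]) + 1)
        ]
        entries.sort(key=lambda e: (e[0], e[1]))
        n = len(entries)
        bwt_chars = []
        sa = np.empty((n, 2), dtype=np.int32)
        for row, (_, r, p) in enumerate(entries):
            bwt_chars.append(seqs[r][p - 1] if p > 0 else SENTINEL)
            sa[row, 0] = r
            sa[row, 1] = p
        self.bwt = "".join(bwt_chars)
        self.sa = sa  # full suffix-array samples: (local read, offset) per row

        alphabet = sorted(set(self.bwt))
        self._chars = alphabet
        codes = np.frombuffer(self.bwt.encode("ascii"), dtype=np.uint8)
        counts = {}
        occ = {}
        for c in alphabet:
            mask = codes == ord(c)
            counts[c] = int(mask.sum())
            # occ[c][i] = number of c in bwt[:i]
            cum = np.zeros(n + 1, dtype=np.int32)
            np.cumsum(mask, dtype=np.int32, out=cum[1:])
            occ[c] = cum
        self._occ = occ
        # C array: number of characters strictly smaller than c in the text.
        cum = 0
        C = {}
        for c in alphabet:
            C[c] = cum
            cum += counts[c]
        self._C = C
        self.size = n

    # -- queries -----------------------------------------------------------

    @property
    def n_reads(self) -> int:
        return len(self.sequences)

    def full_interval(self) -> FmInterval:
        return FmInterval(0, self.size)

    def extend_left(self, interval: FmInterval, char: str) -> FmInterval:
        """One backward-search step: occurrences of ``char + current pattern``."""
        if char == AMBIGUOUS or char not in self._C:
            return FmInterval(0, 0)
        if interval.empty:
            return FmInterval(0, 0)
        occ = self._occ[char]
        base = self._C[char]
        return FmInterval(base + int(occ[interval.lower]), base + int(occ[interval.upper]))

    def reconstruct_reads(self) -> list[str]:
        """Invert the BWT; returns the member reads in member order."""
        out = []
        for r in range(self.n_reads):
            # Row r is the sentinel-only suffix of read r (sentinels sort
            # first, ordered by read index).
            chars: list[str] = []
            row = r
            while True:
                c = self.bwt[row]
                if c == SENTINEL:
                    break
                chars.append(c)
                row = self._C[c] + int(self._occ[c][row])
            out.append("".join(reversed(chars)))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BwtBlock):
            return NotImplemented
        return (
            self.block_id == other.block_id
            and self.read_indices == other.read_indices
            and self.sequences == other.sequences
            and self.bwt == other.bwt
            and np.array_equal(self.sa, other.sa)
        )


def build_blocks(reads: Sequence[PeptideRead], block_size: int = 100_000) -> list[BwtBlock]:
    """Partition ``reads`` (in input order) into blocks and index each.

    Raises ``ValueError`` on an empty read set, a non-positive block size,
    a duplicated read id, or an illegal character (naming the read).
    """
    if not reads:
        raise ValueError("cannot index an empty read set")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    seen: set[str] = set()
    for rd in reads:
        if rd.read_id in seen:
            raise ValueError(f"duplicate read_id {rd.read_id!r}")
        seen.add(rd.read_id)
        validate_sequence(rd.sequence, name=f"read {rd.read_id!r}")
    blocks = []
    for b, start in enumerate(range(0, len(reads), block_size)):
        chunk = reads[start : start + block_size]
        blocks.append(
            BwtBlock(
                block_id=b,
                read_indices=list(range(start, start + len(chunk))),
                sequences=[rd.sequence for rd in chunk],
            )
        )
    return blocks


def backward_search(block: BwtBlock, pattern: str) -> FmInterval:
    """FM-index backward search: rows whose suffixes start with ``pattern``.

    The interval width equals the number of occurrences of ``pattern`` as a
    substring across the block's reads. Patterns containing ``X`` match
    nothing by definition.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    interval = block.full_interval()
    for char in reversed(pattern):
        interval = block.extend_left(interval, char)
        if interval.empty:
            return FmInterval(0, 0)
    return interval


def locate(block: BwtBlock, interval: FmInterval) -> list[tuple[int, int]]:
    """Resolve an interval to (global read index, 0-based offset) pairs."""
    if interval.lower < 0 or interval.upper > block.size or interval.lower > interval.upper:
        raise ValueError(f"interval [{interval.lower}, {interval.upper}) out of range")
    hits = []
    for row in range(interval.lower, interval.upper):
        r, p = int(block.sa[row, 0]), int(block.sa[row, 1])
        hits.append((block.read_indices[r], p))
    return hits


def iter_block_reads(blocks: Sequence[BwtBlock]) -> Iterator[tuple[int, str]]:
    """Yield (global read index, sequence) over all blocks in order."""
    for block in blocks:
        yield from zip(block.read_indices, block.sequences)


def all_sequences(blocks: Sequence[BwtBlock]) -> list[str]:
    """Global read sequences indexed by global read index."""
    total = sum(b.n_reads for b in blocks)
    seqs: list[str] = [""] * total
    for idx, seq in iter_block_reads(blocks):
        seqs[idx] = seq
    return seqs
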