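"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (exhaustive scans, full-matrix DP via
biopython) so they stay independent of the implementation paths they
check.
"""

from __future__ import annotations

import random
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from peptig.alphabet import AA20
from peptig.fm_index import PeptideRead


# -- sequence generators ---------------------------------------------------


def random_peptides(
    rng: random.Random, n: int, min_len: int = 5, max_len: int = 40
) -> List[PeptideRead]:
    return [
        PeptideRead(
            f"r{i}",
            "".join(rng.choice(AA20) for _ in range(rng.randint(min_len, max_len))),
        )
        for i in range(n)
    ]


def shredded_reads(
    rng: random.Random, source_len: int = 250, read_len: int = 30, step: int = 7
) -> List[PeptideRead]:
    """Overlapping fixed-length reads tiled over a random source protein."""
    src = "".join(rng.choice(AA20) for _ in range(source_len))
    return [
        PeptideRead(f"r{i}", src[p : p + read_len])
        for i, p in enumerate(range(0, source_len - read_len + 1, step))
    ]


# -- naive oracles ---------------------------------------------------------


def naive_occurrences(sequences: Sequence[str], pattern: str) -> List[Tuple[int, int]]:
    """All (read index, offset) occurrences of pattern, by direct scan."""
    hits = []
    for idx, seq in enumerate(sequences):
        start = 0
        while True:
            p = seq.find(pattern, start)
            if p < 0:
                break
            hits.append((idx, p))
            start = p + 1
    return hits


def naive_max_overlaps(sequences: Sequence[str], l: int) -> Dict[Tuple[int, int], int]:
    """All-pairs maximal proper suffix-prefix overlaps of length >= l."""
    out: Dict[Tuple[int, int], int] = {}
    for s, src in enumerate(sequences):
        for t, tgt in enumerate(sequences):
            if s == t:
                continue
            top = min(len(src), len(tgt) - 1)  # proper: target extends beyond
            for olen in range(top, l - 1, -1):
                if src[len(src) - olen :] == tgt[:olen]:
                    out[(s, t)] = olen
                    break
    return out


def naive_containments(sequences: Sequence[str]) -> Dict[int, int]:
    """contained -> container (longer read, or lower index among duplicates)."""
    out: Dict[int, int] = {}
    for a, sa in enumerate(sequences):
        for b, sb in enumerate(sequences):
            if a == b or a in out:
                continue
            if sa in sb and (len(sa) < len(sb) or (sa == sb and b < a)):
                out[a] = b
                break
    return out


def best_diagonal_segment(query: str, subject: str, seed_q: int, seed_s: int, k: int):
    """Exhaustive best ungapped diagonal sub-segment containing the seed."""
    from peptig.alphabet import score_ungapped

    best = None
    qlo_min = seed_q - min(seed_q, seed_s)
    n_left = min(seed_q, seed_s)
    n_right = min(len(query) - (seed_q + k), len(subject) - (seed_s + k))
    for left in range(n_left + 1):
        for right in range(n_right + 1):
            qs, qe = seed_q - left, seed_q + k + right
            ss = seed_s - left
            sc = score_ungapped(query[qs:qe], subject[ss : ss + (qe - qs)])
            if best is None or sc > best[0]:
                best = (sc, (qs, qe), (ss, ss + (qe - qs)))
    return best


_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
# a gap of length g costs 11 + g (open 11, extend 1)
_aligner.open_gap_score = -12
_aligner.extend_gap_score = -1


def full_smith_waterman_score(a: str, b: str) -> int:
    """Independent full-matrix local alignment score (biopython)."""
    return int(_aligner.score(a, b))


# -- fixtures --------------------------------------------------------------


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(42)


@pytest.fixture()
def nprng() -> np.random.Generator:
    return np.random.default_rng(42)
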