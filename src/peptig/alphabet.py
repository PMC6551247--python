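"""Amino-acid alphabet, scoring matrix, and residue statistics.

The whole package works in protein space: reads, unitigs, contigs and
queries are strings over the 20 canonical amino acids plus ``X`` for
ambiguous residues. ``X`` never matches anything (including itself) during
seeding and exact search; substitution scoring falls back to the BLOSUM62
``X`` column during gapped alignment.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 canonical amino acids, alphabetically ordered one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity character; excluded from seeding and exact matching.
AMBIGUOUS = "X"

#: Characters legal in a peptide read.
READ_ALPHABET = frozenset(AA20) | {AMBIGUOUS}

#: Per-read terminator used by the multi-string BWT; lexicographically
#: smaller than every residue.
SENTINEL = "$"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# Dense lookup keyed by ordinals for speed; unknown pairs score as X.
_SCORE = {}
for _a in _BLOSUM62.alphabet:
    for _b in _BLOSUM62.alphabet:
        _SCORE[(_a, _b)] = int(_BLOSUM62[_a, _b])


def blosum62(a: str, b: str) -> int:
    """BLOSUM62 substitution score for a residue pair (integer units)."""
    return _SCORE.get((a, b), _SCORE[("X", "X")])


def score_ungapped(x: str, y: str) -> int:
    """Sum of BLOSUM62 scores over two equal-length strings."""
    if len(x) != len(y):
        raise ValueError("ungapped scoring requires equal lengths")
    return sum(_SCORE.get((a, b), _SCORE[("X", "X")]) for a, b in zip(x, y))


#: Average amino-acid frequencies close to the SwissProt composition,
#: used as the default background for synthetic proteomes.
BACKGROUND_FREQS = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0394, "R": 0.0553,
    "S": 0.0664, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

_BG_RESIDUES = np.array(list(BACKGROUND_FREQS))
_BG_P = np.array(list(BACKGROUND_FREQS.values()))
_BG_P = _BG_P / _BG_P.sum()


def random_protein(length: int, rng: np.random.Generator, uniform: bool = False) -> str:
    """Draw a random protein sequence from the background composition."""
    if uniform:
        return "".join(rng.choice(list(AA20), size=length))
    return "".join(rng.choice(_BG_RESIDUES, size=length, p=_BG_P))


def validate_sequence(seq: str, *, name: str = "sequence") -> None:
    """Raise ``ValueError`` naming the offender if ``seq`` is not a legal read."""
    if len(seq) < 1:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - READ_ALPHABET
    if bad:
        raise ValueError(
            f"{name}: illegal character(s) {sorted(bad)!r}; allowed are the 20 "
            f"canonical amino acids and 'X'"
        )
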