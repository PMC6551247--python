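"""Run configuration: every tunable, validated, serialized with outputs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Attributes
    ----------
    min_overlap:
        Minimum suffix-prefix overlap (residues) for a string-graph edge.
    seed_k:
        Seed k-mer length for anchoring and read mapping.
    block_size:
        Reads per BWT block.
    bubble_depth:
        Maximum nodes explored in each direction during bubble popping.
    anchor_threshold:
        Minimum ungapped score (BLOSUM62 units) for an anchor.
    xdrop:
        Ungapped extension termination margin.
    gap_open / gap_extend:
        Affine gap penalties (a length-g gap costs open + g * extend).
    lam / k_param:
        Karlin-Altschul gapped parameters for E-values
        (comparator-calibrated, configurable).
    evalue_cutoff:
        Contig acceptance threshold.
    min_identity / min_span:
        Read recruitment thresholds (fractions).
    path_slack:
        Candidate-path length tolerance relative to the query length.
    max_paths_per_anchor:
        Cap on DFS branch combinations per anchor.
    rng_seed:
        Seed for every stochastic component.
    """

    min_overlap: int = 10
    seed_k: int = 6
    block_size: int = 100_000
    bubble_depth: int = 10
    anchor_threshold: int = 25
    xdrop: int = 20
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k_param: float = 0.041
    evalue_cutoff: float = 1e-3
    min_identity: float = 0.9
    min_span: float = 0.8
    path_slack: float = 0.2
    max_paths_per_anchor: int = 64
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap < 1 or self.seed_k < 1 or self.block_size < 1:
            raise ValueError("min_overlap, seed_k and block_size must be >= 1")
        if self.bubble_depth < 1 or self.max_paths_per_anchor < 1:
            raise ValueError("bubble_depth and max_paths_per_anchor must be >= 1")
        if self.gap_open < 0 or self.gap_extend < 0 or self.xdrop < 0:
            raise ValueError("penalties must be non-negative")
        if self.lam <= 0 or self.k_param <= 0 or self.evalue_cutoff <= 0:
            raise ValueError("lam, k_param and evalue_cutoff must be positive")
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.min_span <= 1.0):
            raise ValueError("min_identity and min_span must lie in [0, 1]")
        if self.path_slack < 0:
            raise ValueError("path_slack must be non-negative")

    def to_json(self, path: str | Path) -> None:
        from .io import _atomic_write

        _atomic_write(path, lambda fh: json.dump(asdict(self), fh, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
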