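"""Synthetic peptide communities with planted homologs and ground truth.

The generator emulates, directly in amino-acid space, the construction of
a simulated metagenomic benchmark: random background proteomes stand in
for core genomes, homolog copies of each query protein are planted at a
controlled divergence, and fixed-length error-bearing peptide reads are
shredded from the proteomes at a target coverage with their true origins
recorded. Reads are labeled homolog / non-homolog / boundary against the
planted intervals; boundary reads (straddling a homolog-region endpoint)
belong to neither truth set and are excluded from scoring.

Defaults mirror the short-read regime the method targets: 33-residue reads
(about 100 bp of coding sequence), 10X coverage, 1% per-residue error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .alphabet import AA20, blosum62, random_protein
from .fm_index import PeptideRead, ReadOrigin

__all__ = [
    "PlantedHomolog",
    "SyntheticCommunity",
    "GroundTruthLabel",
    "generate_community",
    "shred_reads",
]

DEFAULT_READ_LENGTH = 33
DEFAULT_COVERAGE = 10.0
DEFAULT_ERROR_RATE = 0.01
DEFAULT_QUERY_LENGTH = 150


@dataclass(frozen=True)
class PlantedHomolog:
    """A homolog copy of ``query_id`` planted in ``genome_id`` at [start, end)."""

    query_id: str
    genome_id: str
    start: int
    end: int
    target_identity: float
    realized_identity: float


@dataclass
class SyntheticCommunity:
    """Background proteomes plus planted homolog records."""

    proteomes: Dict[str, str]
    queries: Dict[str, str]
    planted_homologs: List[PlantedHomolog]
    rng_seed: int


@dataclass(frozen=True)
class GroundTruthLabel:
    read_id: str
    label: Literal["homolog", "non_homolog", "boundary"]
    query_id: Optional[str] = None


_AA_LIST = list(AA20)
# BLOSUM62-biased substitution weights: P(b | a) proportional to
# 2^(score(a,b)/2) over b != a, so mutations favour chemically similar
# residues as real divergence does.
_SUB_WEIGHTS: Dict[str, Tuple[List[str], np.ndarray]] = {}
for _a in _AA_LIST:
    others = [b for b in _AA_LIST if b != _a]
    w = np.array([2.0 ** (blosum62(_a, b) / 2.0) for b in others])
    _SUB_WEIGHTS[_a] = (others, w / w.sum())


def _mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> Tuple[str, float]:
    n = len(seq)
    n_sub = round((1.0 - identity) * n)
    if identity < 1.0 and n_sub == 0:
        raise ValueError(
            f"target identity {identity} rounds to zero substitutions at length {n}"
        )
    positions = rng.choice(n, size=n_sub, replace=False) if n_sub else np.array([], dtype=int)
    chars = list(seq)
    for p in positions:
        options, probs = _SUB_WEIGHTS[chars[p]]
        chars[p] = str(rng.choice(options, p=probs))
    realized = (n - n_sub) / n
    return "".join(chars), realized


def generate_community(
    n_genomes: int,
    genome_length: int,
    n_queries: int,
    homolog_identity: float,
    seed: int,
    copies_per_query: int = 2,
    query_length: int = DEFAULT_QUERY_LENGTH,
) -> SyntheticCommunity:
    """Build a community with planted homolog regions.

    Each query is a random protein; ``copies_per_query`` independently
    mutated copies at the target identity are planted into distinct
    genomes (round-robin) at non-overlapping coordinates. Fully
    reproducible from ``seed``.
    """
    if min(n_genomes, genome_length, n_queries) < 1:
        raise ValueError("all sizes must be >= 1")
    if not (0.4 < homolog_identity <= 1.0):
        raise ValueError("homolog_identity must lie in (0.4, 1.0]")
    if query_length > genome_length:
        raise ValueError("queries must fit inside a genome")
    rng = np.random.default_rng(seed)
    genome_ids = [f"g{i}" for i in range(n_genomes)]
    proteomes = {gid: random_protein(genome_length, rng) for gid in genome_ids}
    queries = {f"q{i}": random_protein(query_length, rng) for i in range(n_queries)}

    slots: Dict[str, List[Tuple[int, int]]] = {gid: [] for gid in genome_ids}
    planted: List[PlantedHomolog] = []
    turn = 0
    for qid, qseq in sorted(queries.items()):
        for _ in range(copies_per_query):
            gid = genome_ids[turn % n_genomes]
            turn += 1
            start = _find_slot(slots[gid], genome_length, len(qseq), rng)
            if start is None:
                continue  # genome is saturated; skip this copy
            copy, realized = _mutate_to_identity(qseq, homolog_identity, rng)
            g = proteomes[gid]
            proteomes[gid] = g[:start] + copy + g[start + len(copy) :]
            slots[gid].append((start, start + len(copy)))
            planted.append(
                PlantedHomolog(qid, gid, start, start + len(copy), homolog_identity, realized)
            )
    return SyntheticCommunity(proteomes, queries, planted, rng_seed=seed)


def _find_slot(
    taken: List[Tuple[int, int]], genome_length: int, size: int, rng: np.random.Generator
) -> Optional[int]:
    for _ in range(200):
        start = int(rng.integers(0, genome_length - size + 1))
        if all(start + size <= s or start >= e for s, e in taken):
            return start
    return None


def shred_reads(
    community: SyntheticCommunity,
    read_length: int = DEFAULT_READ_LENGTH,
    coverage: float = DEFAULT_COVERAGE,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> Tuple[List[PeptideRead], List[GroundTruthLabel]]:
    """Shred fixed-length reads with substitution errors and label them.

    Uniform random start positions at expected depth ``coverage``;
    per-residue substitution errors at ``error_rate`` (uniform over the
    other 19 residues). A read fully inside a planted interval is labeled
    ``homolog`` (carrying the query id); one straddling an endpoint is
    ``boundary``; everything else is ``non_homolog``.
    """
    rng = np.random.default_rng(seed)
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    reads: List[PeptideRead] = []
    labels: List[GroundTruthLabel] = []
    regions = {gid: [] for gid in community.proteomes}
    for ph in community.planted_homologs:
        regions[ph.genome_id].append(ph)
    for gid in sorted(community.proteomes):
        genome = community.proteomes[gid]
        glen = len(genome)
        if read_length > glen:
            raise ValueError("read_length exceeds genome length")
        n_reads = int(round(coverage * glen / read_length))
        starts = rng.integers(0, glen - read_length + 1, size=n_reads)
        for i, start in enumerate(map(int, starts)):
            end = start + read_length
            seq = genome[start:end]
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(read_length) < error_rate)
                if errs.size:
                    chars = list(seq)
                    for p in errs:
                        alternatives = [c for c in _AA_LIST if c != chars[p]]
                        chars[p] = str(rng.choice(alternatives))
                    seq = "".join(chars)
            rid = f"{gid}_r{i}"
            reads.append(PeptideRead(rid, seq, ReadOrigin(gid, start, end)))
            labels.append(_label_read(rid, start, end, regions[gid]))
    return reads, labels


def _label_read(
    rid: str, start: int, end: int, regions: Sequence[PlantedHomolog]
) -> GroundTruthLabel:
    for ph in regions:
        if start >= ph.start and end <= ph.end:
            return GroundTruthLabel(rid, "homolog", ph.query_id)
    for ph in regions:
        if start < ph.end and end > ph.start:  # partial overlap
            return GroundTruthLabel(rid, "boundary", ph.query_id)
    return GroundTruthLabel(rid, "non_homolog")
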