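"""End-to-end pipeline: index build, homolog assembly, read recruitment."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .config import RunConfig
from .fm_index import PeptideRead, build_blocks
from .homology_search import HomologContig, assemble_homologs, index_seeds
from .read_recruitment import RecruitedRead, recruit
from .string_graph import UnitigGraph, build_unitig_graph

logger = logging.getLogger("peptig")


@dataclass
class PipelineResult:
    config: RunConfig
    unitig_graph: UnitigGraph
    contigs: List[HomologContig]
    recruited: List[RecruitedRead]
    stage_seconds: Dict[str, float] = field(default_factory=dict)


def build_index_from_reads(
    reads: Sequence[PeptideRead], config: RunConfig
) -> Tuple[list, UnitigGraph]:
    """Blockwise FM-index construction plus the full graph stage."""
    blocks = build_blocks(reads, block_size=config.block_size)
    ugraph = build_unitig_graph(
        blocks, l=config.min_overlap, bubble_depth=config.bubble_depth
    )
    return blocks, ugraph


def search_queries(
    queries: Dict[str, str],
    unitig_graph: UnitigGraph,
    database_residues: int,
    config: RunConfig,
    evalue_cutoff: Optional[float] = None,
) -> List[HomologContig]:
    """Run the homolog search for every query; contig ids are globally unique."""
    seed_index = index_seeds(unitig_graph, k=config.seed_k)
    contigs: List[HomologContig] = []
    for qid in sorted(queries):
        hits = assemble_homologs(
            qid,
            queries[qid],
            unitig_graph,
            seed_index,
            database_residues,
            evalue_cutoff=config.evalue_cutoff if evalue_cutoff is None else evalue_cutoff,
            anchor_threshold=config.anchor_threshold,
            xdrop=config.xdrop,
            slack=config.path_slack,
            max_paths_per_anchor=config.max_paths_per_anchor,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            lam=config.lam,
            k_param=config.k_param,
        )
        for h in hits:
            h.contig_id = len(contigs)
            contigs.append(h)
    return contigs


def run_pipeline(
    reads: Sequence[PeptideRead],
    queries: Dict[str, str],
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    """build -> assemble -> map, with stage timings and counts logged."""
    config = config or RunConfig()
    t0 = time.perf_counter()
    blocks, ugraph = build_index_from_reads(reads, config)
    t1 = time.perf_counter()
    db_residues = sum(len(r.sequence) for r in reads)
    contigs = search_queries(queries, ugraph, db_residues, config)
    t2 = time.perf_counter()
    recruited = recruit(
        contigs,
        reads,
        min_identity=config.min_identity,
        min_span=config.min_span,
        k=config.seed_k,
    )
    t3 = time.perf_counter()
    timings = {"build": t1 - t0, "assemble": t2 - t1, "map": t3 - t2}
    logger.info(
        "reads=%d unitigs=%d contigs=%d recruited=%d timings=%s",
        len(reads),
        len(ugraph.unitigs),
        len(contigs),
        len(recruited),
        {k: round(v, 2) for k, v in timings.items()},
    )
    return PipelineResult(config, ugraph, contigs, recruited, timings)
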