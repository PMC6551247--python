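"""File formats: FASTA in/out, on-disk index, GFA-like unitig export.

The index directory layout (version 1):

    manifest.json          parameters, counts, format version
    block_<i>.json         per-block BWT, suffix-array samples, members
    unitigs.gfa            S lines (unitig sequences), L lines (links)
    members.tsv            read placements inside unitigs

Reload is bit-exact: a reloaded block compares equal to the rebuilt one.
All writes are atomic (write to a temp name, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fm_index import BwtBlock, PeptideRead
from .string_graph import Unitig, UnitigGraph

INDEX_FORMAT_VERSION = 1


# -- FASTA -----------------------------------------------------------------


def read_fasta_reads(path: str | Path) -> List[PeptideRead]:
    """Load peptide reads from FASTA (ids must be unique)."""
    reads = [
        PeptideRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not reads:
        raise ValueError(f"no sequences found in {path}")
    return reads


def read_fasta_queries(path: str | Path) -> Dict[str, str]:
    queries = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not queries:
        raise ValueError(f"no sequences found in {path}")
    return queries


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    _atomic_write(path, lambda fh: SeqIO.write(recs, fh, "fasta"))


# -- atomic writes ---------------------------------------------------------


def _atomic_write(path: str | Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- index persistence -----------------------------------------------------


def save_index(
    out_dir: str | Path,
    blocks: Sequence[BwtBlock],
    unitig_graph: UnitigGraph,
    reads: Sequence[PeptideRead],
    config: Optional[dict] = None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for block in blocks:
        payload = {
            "block_id": block.block_id,
            "read_indices": block.read_indices,
            "sequences": block.sequences,
            "bwt": block.bwt,
            "sa": block.sa.tolist(),
        }
        _atomic_write(
            out_dir / f"block_{block.block_id}.json",
            lambda fh, p=payload: json.dump(p, fh),
        )
    write_fasta(((r.read_id, r.sequence) for r in reads), out_dir / "reads.faa")
    export_unitigs_gfa(unitig_graph, out_dir / "unitigs.gfa")
    export_members_tsv(unitig_graph, reads, out_dir / "members.tsv")
    manifest = {
        "format_version": INDEX_FORMAT_VERSION,
        "n_blocks": len(blocks),
        "n_reads": len(reads),
        "n_unitigs": len(unitig_graph.unitigs),
        "database_residues": sum(len(r.sequence) for r in reads),
        "config": config or {},
    }
    _atomic_write(out_dir / "manifest.json", lambda fh: json.dump(manifest, fh, indent=2))


def load_index(
    index_dir: str | Path,
) -> Tuple[dict, List[BwtBlock], UnitigGraph, List[PeptideRead]]:
    index_dir = Path(index_dir)
    manifest_path = index_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {index_dir}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(
            f"incompatible index version {manifest.get('format_version')!r}; "
            f"expected {INDEX_FORMAT_VERSION}"
        )
    blocks = []
    for b in range(manifest["n_blocks"]):
        payload = json.loads((index_dir / f"block_{b}.json").read_text())
        block = BwtBlock(payload["block_id"], payload["read_indices"], payload["sequences"])
        # bit-exact check against the stored structures
        if block.bwt != payload["bwt"] or not np.array_equal(
            block.sa, np.asarray(payload["sa"], dtype=np.int32)
        ):
            raise ValueError(f"index block {b} is corrupt (rebuild mismatch)")
        blocks.append(block)
    reads = read_fasta_reads(index_dir / "reads.faa")
    unitig_graph = import_unitigs_gfa(index_dir / "unitigs.gfa", index_dir / "members.tsv")
    return manifest, blocks, unitig_graph, reads


# -- unitig export ---------------------------------------------------------


def export_unitigs_gfa(graph: UnitigGraph, path: str | Path) -> None:
    def writer(fh):
        fh.write("H\tVN:Z:1.0\n")
        for u in graph.unitigs:
            fh.write(f"S\tu{u.unitig_id}\t{u.sequence}\n")
        for a, b, olen in graph.edges():
            fh.write(f"L\tu{a}\t+\tu{b}\t+\t{olen}M\n")

    _atomic_write(path, writer)


def export_members_tsv(
    graph: UnitigGraph, reads: Sequence[PeptideRead], path: str | Path
) -> None:
    def writer(fh):
        fh.write("unitig_id\tread_index\tread_id\toffset\n")
        for u in graph.unitigs:
            for read_idx, off in u.members:
                rid = reads[read_idx].read_id if read_idx < len(reads) else str(read_idx)
                fh.write(f"{u.unitig_id}\t{read_idx}\t{rid}\t{off}\n")

    _atomic_write(path, writer)


def import_unitigs_gfa(gfa_path: str | Path, members_path: str | Path) -> UnitigGraph:
    sequences: Dict[int, str] = {}
    edges: List[Tuple[int, int, int]] = []
    for line in Path(gfa_path).read_text().splitlines():
        parts = line.split("\t")
        if parts[0] == "S":
            sequences[int(parts[1][1:])] = parts[2]
        elif parts[0] == "L":
            edges.append((int(parts[1][1:]), int(parts[3][1:]), int(parts[5][:-1])))
    members: Dict[int, List[Tuple[int, int]]] = {uid: [] for uid in sequences}
    lines = Path(members_path).read_text().splitlines()
    for line in lines[1:]:
        uid, read_idx, _rid, off = line.split("\t")
        members[int(uid)].append((int(read_idx), int(off)))
    unitigs = [
        Unitig(uid, seq, members=members.get(uid, []), path=[])
        for uid, seq in sorted(sequences.items())
    ]
    return UnitigGraph(unitigs, edges)


# -- tabular outputs -------------------------------------------------------


def write_alignment_table(contigs, query_lengths: Dict[str, str] | Dict[str, int], path: str | Path) -> None:
    """12-column tabular alignment layout (BLAST outfmt-6-like).

    Columns: query, contig, pct identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, evalue, bitscore-like score.
    Coordinates are 1-based inclusive as in the classic dialect.
    """
    from .homology_search import expand_edit_string

    def writer(fh):
        for c in contigs:
            runs = expand_edit_string(c.alignment.edit_string)
            matches = sum(n for n, op in runs if op == "=")
            mism = sum(n for n, op in runs if op == "X")
            gapopens = sum(1 for _, op in runs if op in "ID")
            alnlen = sum(n for n, _ in runs)
            qs, qe = c.alignment.query_interval
            ss, se = c.alignment.path_interval
            pid = 100.0 * matches / alnlen if alnlen else 0.0
            fh.write(
                f"{c.query_id}\tcontig_{c.contig_id}\t{pid:.2f}\t{alnlen}\t{mism}\t"
                f"{gapopens}\t{qs + 1}\t{qe}\t{ss + 1}\t{se}\t{c.evalue:.3g}\t{c.score}\n"
            )

    _atomic_write(path, writer)


def write_recruitment_tsv(recruited, path: str | Path) -> None:
    def writer(fh):
        fh.write("read_id\tquery_id\tcontig_id\tpos\tidentity\tevalue\n")
        for r in recruited:
            fh.write(
                f"{r.read_id}\t{r.assigned_query}\tcontig_{r.contig_id}\t{r.contig_pos}\t"
                f"{r.identity:.4f}\t{r.assigned_evalue:.3g}\n"
            )

    _atomic_write(path, writer)


def write_truth_tsv(labels, path: str | Path) -> None:
    def writer(fh):
        fh.write("read_id\tlabel\tquery_id\n")
        for t in labels:
            fh.write(f"{t.read_id}\t{t.label}\t{t.query_id or ''}\n")

    _atomic_write(path, writer)


def read_truth_tsv(path: str | Path):
    from .synthetic_data import GroundTruthLabel

    labels = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        rid, label, qid = line.split("\t")
        labels.append(GroundTruthLabel(rid, label, qid or None))
    return labels


def read_recruitment_tsv(path: str | Path):
    from .read_recruitment import RecruitedRead

    out = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        rid, qid, cid, pos, ident, ev = line.split("\t")
        out.append(
            RecruitedRead(rid, int(cid.split("_")[1]), int(pos), float(ident), qid, float(ev))
        )
    return out
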