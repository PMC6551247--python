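# peptig

Gene-centric assembly and homolog search for short-peptide metagenomic
reads.

## The problem

Functional annotation of a metagenome usually means deciding, for every
sequencing read, whether it derives from a homolog of some reference
protein. Individual short peptide reads (20–60 residues, typically
produced by gene calling on ~100 bp nucleotide reads) carry too little
signal for remote-homology detection: a read that shares no exact seed
with the query is invisible to seed-and-extend search tools, and whole
de novo assembly discards the low-abundance polymorphism that gene-centric
questions care about.

`peptig` instead assembles *only what the query asks for*. It builds an
SNP-aware string graph over the entire peptide read set once, then, per
reference protein, finds graph paths that spell homologous sequences and
uses those assembled contigs as templates to recruit the original reads.
A read with no shared seed is still recovered whenever it overlaps reads
that do carry seeds — that is the sensitivity advantage of the
contig-mediated route.

## Method

1. **Blockwise FM-index.** The read set is partitioned into blocks; each
   block gets a multi-string BWT/FM-index (one sentinel per read). Block
   size bounds indexing memory.
2. **String graph.** For each read, all blocks are queried by a single
   incremental backward search to find maximal suffix–prefix overlaps of
   length ≥ *l* (default 10 aa). Contained reads are removed where
   detected; cross-block containment artifacts survive as parallel paths
   or dead ends and are rectified by bubble removal (a branch is deleted
   **only** when the two spellings are identical — substitutions are
   kept) and tip trimming (a dead end is deleted only when its spelling
   is contained in a neighboring through-path). Transitive edges are
   reduced canonically; unbranched paths collapse into unitigs.
3. **Homolog search.** Exact *k*-mer seeds (default *k* = 6) between
   query and unitigs are extended into ungapped BLOSUM62 anchors under an
   X-drop rule; anchors are ranked by score; depth-first traversal grows
   each surviving anchor into candidate paths whose spelled length
   matches the query length, claiming unitigs so each graph region is
   traversed once (best anchors first). Each candidate path is scored by
   a banded Smith–Waterman with affine gaps (open 11, extend 1) and
   assigned a Karlin–Altschul E-value `E = K·m·n·e^(−λS)`; passing paths
   are emitted as homolog contigs.
4. **Read recruitment.** Reads map onto the contigs by exact 6-mer
   seeding plus banded verification; a read is recruited when it aligns
   at ≥ 90% identity over ≥ 80% of its length inside the contig's
   query-aligned interval.

Recruitment is scored against ground truth as recall = TP/(TP+FN) and
precision = TP/(TP+FP), with reads straddling a homolog-region boundary
excluded from both truth sets.

## Worked example

The built-in simulator plants divergent homolog copies of random query
proteins into random background proteomes and shreds error-bearing
fixed-length reads with recorded origins:

```sh
peptig simulate --genomes 4 --genome-length 800 --queries 1 \
    --identity 0.75 --coverage 10 --read-len 33 --error 0.01 --seed 7 -o sim
peptig build -i sim/reads.faa -o index
peptig assemble -q sim/queries.faa -d index -o out -e 1e-3
peptig map -d index -c out.contigs.json -o out.reads.tsv
peptig eval -p out.reads.tsv -t sim/truth.tsv -o metrics.tsv --roc roc.tsv
```

prints

```
968 reads, 1 queries -> sim
indexed 968 reads into 452 unitigs -> index
27 homolog contig(s) -> out.contigs.faa
recruited 90 read(s) -> out.reads.tsv
pooled recall=1.0000 precision=1.0000 -> metrics.tsv
```

`metrics.tsv` holds the pooled and per-query counts; here every one of
the 76 interior homolog reads was recruited (recall 1.0) with no
non-homolog read recruited (precision 1.0), even though the planted
copies are only 75% identical to the query. `out.aln.tsv` is a 12-column
BLAST-outfmt-6-like table (query, contig, % identity, alignment length,
mismatches, gap opens, qstart, qend, sstart, send, E-value, score); its
top line

```
q0  contig_0  74.67  150  38  0  1  150  34  183  4.01e-65  601
```

shows a contig aligning over the full 150-residue query at 74.7%
identity — the planted divergence recovered from 33-residue reads.
`out.reads.tsv` lists each recruited read with its contig placement,
identity, and the contig's E-value.

Everything is also available as a library (`peptig.run_pipeline`,
`peptig.generate_community`, ...), which is what the test-suite and the
acceptance script use.

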