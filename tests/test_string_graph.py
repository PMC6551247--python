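"""String graph: overlaps, containments, cleanup, unitig collapsing."""

import random

import pytest

from peptig.fm_index import PeptideRead, build_blocks, all_sequences
from peptig.string_graph import (
    Containment,
    Overlap,
    StringGraph,
    build_graph,
    build_unitig_graph,
    collapse_unitigs,
    find_overlaps,
    remove_bubbles,
    transitive_reduction,
    trim_tips,
)

from conftest import naive_containments, naive_max_overlaps, random_peptides, shredded_reads


def _graph_from(reads, l=10, n_blocks=1):
    bs = max(1, (len(reads) + n_blocks - 1) // n_blocks)
    blocks = build_blocks(reads, bs)
    ov, ct = find_overlaps(blocks, l=l)
    return build_graph(ov, ct, all_sequences(blocks)), ov, ct


# -- overlap detection -----------------------------------------------------


def test_constructed_overlap_depends_on_minimum_length():
    reads = [PeptideRead("a", "MKVLITAAGHLK"), PeptideRead("b", "TAAGHLKWQERS")]
    blocks = build_blocks(reads, 10)
    ov5, _ = find_overlaps(blocks, l=5)
    assert ov5 == [Overlap(0, 1, 7)]
    ov10, _ = find_overlaps(blocks, l=10)
    assert ov10 == []


def test_substring_read_is_containment_not_overlap():
    reads = [PeptideRead("big", "MKVLITAAGHLKWQ"), PeptideRead("small", "ITAAGH")]
    ov, ct = find_overlaps(build_blocks(reads, 10), l=3)
    assert ct == [Containment(contained=1, container=0, offset=4)]
    assert all(o.source != 1 and o.target != 1 for o in ov)


def test_exact_duplicates_resolve_to_lower_index_container():
    reads = [PeptideRead("a", "MKVLITAAGHLK"), PeptideRead("b", "MKVLITAAGHLK")]
    _, ct = find_overlaps(build_blocks(reads, 10), l=5)
    assert ct == [Containment(contained=1, container=0, offset=0)]


def test_minimum_overlap_larger_than_reads_warns_and_returns_empty():
    reads = [PeptideRead("a", "MKVLI"), PeptideRead("b", "KVLIT")]
    with pytest.warns(UserWarning):
        ov, ct = find_overlaps(build_blocks(reads, 10), l=50)
    assert ov == [] and ct == []


@pytest.mark.parametrize("l", [5, 10, 15])
def test_single_block_overlaps_match_all_pairs_oracle(l):
    rng = random.Random(l)
    reads = shredded_reads(rng, source_len=220, read_len=28, step=5) + random_peptides(
        rng, 20, 16, 35
    )
    # re-id to keep ids unique
    reads = [PeptideRead(f"x{i}", r.sequence) for i, r in enumerate(reads)]
    seqs = [r.sequence for r in reads]
    _, ov, ct = (None, *find_overlaps(build_blocks(reads, 10_000), l=l))
    contained = naive_containments(seqs)
    assert {c.contained: c.container for c in ct} == contained
    expected = {
        (s, t): olen
        for (s, t), olen in naive_max_overlaps(seqs, l).items()
        if s not in contained and t not in contained
    }
    got = {(o.source, o.target): o.length for o in ov if o.source not in contained and o.target not in contained}
    assert got == expected


# -- graph construction ----------------------------------------------------


def test_perfect_chain_yields_path_graph():
    reads = [
        PeptideRead("a", "MKVLITAAGHLK"),
        PeptideRead("b", "TAAGHLKWQERS"),
        PeptideRead("c", "KWQERSPDNMYF"),
    ]
    g, ov, ct = _graph_from(reads, l=5)
    assert g.nodes == {0, 1, 2}
    assert g.n_edges == 2
    assert g.spell([0, 1, 2]) == "MKVLITAAGHLKWQERSPDNMYF"


def test_edge_spelling_reconstructs_target_read():
    reads = [PeptideRead("a", "MKVLITAAGHLK"), PeptideRead("b", "TAAGHLKWQERS")]
    g, _, _ = _graph_from(reads, l=5)
    spelled = g.spell([0, 1])
    assert reads[1].sequence in spelled and spelled.startswith(reads[0].sequence)


def test_inconsistent_overlap_raises():
    g = StringGraph(["MKVLIT", "WQERSA"])
    with pytest.raises(ValueError, match="inconsistent"):
        g.add_edge(0, 1, 3)


# -- bubbles ---------------------------------------------------------------


def _bubble_graph(mid_b: str):
    """v -> {a, b} -> u diamond; branch spellings differ iff mid_b differs.

    The interior reads overlap v by 8 and u by 6, leaving two free
    residues (positions 8-9) where a polymorphism can sit.
    """
    v = "MKVLITAAGHLKWQ"
    a = "AAGHLKWQTIERSPDN"
    u = "ERSPDNMYFQCHTE"
    seqs = [v, a, mid_b, u]
    g = StringGraph(seqs)
    for n in range(4):
        g.add_node(n)
    g.add_edge(0, 1, 8)
    g.add_edge(0, 2, 8)
    g.add_edge(1, 3, 6)
    g.add_edge(2, 3, 6)
    return g


def test_identical_bubble_collapses_to_one_branch():
    g = _bubble_graph("AAGHLKWQTIERSPDN")  # same spelling as branch a
    remove_bubbles(g, depth=5)
    assert len(g.nodes) == 3  # one interior node survives
    assert g.n_edges == 2


def test_snp_bubble_is_retained():
    g = _bubble_graph("AAGHLKWQTCERSPDN")  # one substitution (I->C)
    before_edges = g.n_edges
    remove_bubbles(g, depth=5)
    assert len(g.nodes) == 4 and g.n_edges == before_edges


def test_bubble_free_graph_is_fixed_point():
    reads = [
        PeptideRead("a", "MKVLITAAGHLK"),
        PeptideRead("b", "TAAGHLKWQERS"),
        PeptideRead("c", "KWQERSPDNMYF"),
    ]
    g, _, _ = _graph_from(reads, l=5)
    nodes, edges = set(g.nodes), g.n_edges
    remove_bubbles(g, depth=5)
    assert g.nodes == nodes and g.n_edges == edges


# -- tips ------------------------------------------------------------------


def test_redundant_tip_is_trimmed():
    # through-path v->b->u; tip v->t where t's spelling is inside the path
    v = "MKVLITAAGHLKWQ"
    b = "AAGHLKWQERSPDN"
    u = "ERSPDNMYFQCHTE"
    t = "AAGHLKWQER"  # prefix of b: tip spelling contained in through-path
    g = StringGraph([v, b, u, t])
    for n in range(4):
        g.add_node(n)
    g.add_edge(0, 1, 8)
    g.add_edge(1, 2, 6)
    g.add_edge(0, 3, 8)
    trim_tips(g)
    assert g.nodes == {0, 1, 2}


def test_orphan_two_node_component_is_retained():
    g = StringGraph(["MKVLITAAGHLK", "TAAGHLKWQERS"])
    g.add_node(0)
    g.add_node(1)
    g.add_edge(0, 1, 7)
    trim_tips(g)
    assert g.nodes == {0, 1}


def test_tip_with_unique_residue_is_retained():
    v = "MKVLITAAGHLKWQ"
    b = "AAGHLKWQERSPDN"
    u = "ERSPDNMYFQCHTE"
    t = "AAGHLKWQCC"  # CC absent from the through-path spelling
    g = StringGraph([v, b, u, t])
    for n in range(4):
        g.add_node(n)
    g.add_edge(0, 1, 8)
    g.add_edge(1, 2, 6)
    g.add_edge(0, 3, 8)
    trim_tips(g)
    assert 3 in g.nodes


# -- unitig collapsing -----------------------------------------------------


def test_linear_chain_collapses_to_single_unitig(rng):
    reads = shredded_reads(rng, source_len=150, read_len=30, step=6)
    ug = build_unitig_graph(build_blocks(reads, 1000), l=10)
    assert len(ug.unitigs) == 1
    u = ug.unitigs[0]
    # every member read occurs verbatim at its recorded offset
    for idx, off in u.members:
        assert u.sequence[off : off + len(reads[idx].sequence)] == reads[idx].sequence


def test_isolated_read_is_its_own_unitig():
    reads = [PeptideRead("solo", "MKVLITAAGHLKWQERS")]
    ug = build_unitig_graph(build_blocks(reads, 10), l=10)
    assert [u.sequence for u in ug.unitigs] == ["MKVLITAAGHLKWQERS"]


def test_unitig_boundaries_coincide_with_branch_nodes(rng):
    # Y-shaped graph: shared stem, two diverging arms
    stem = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(60))
    armA = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(45))
    armB = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(45))
    srcA, srcB = stem + armA, stem + armB
    reads = []
    for i, p in enumerate(range(0, len(srcA) - 30 + 1, 6)):
        reads.append(PeptideRead(f"a{i}", srcA[p : p + 30]))
    for i, p in enumerate(range(0, len(srcB) - 30 + 1, 6)):
        reads.append(PeptideRead(f"b{i}", srcB[p : p + 30]))
    ug = build_unitig_graph(build_blocks(reads, 10_000), l=10)
    # brute-force unipath enumeration predicts three unitigs: stem + 2 arms
    assert len(ug.unitigs) == 3
    spell_set = {u.sequence for u in ug.unitigs}
    assert any(s in srcA and s in srcB for s in spell_set)  # shared stem piece


def test_walk_spelling_matches_read_path_spelling(rng):
    reads = shredded_reads(rng, source_len=200, read_len=30, step=9)
    blocks = build_blocks(reads, 10_000)
    ov, ct = find_overlaps(blocks, l=10)
    g = build_graph(ov, ct, all_sequences(blocks))
    transitive_reduction(g)
    ug = collapse_unitigs(g)
    for u in ug.unitigs:
        assert g.spell(u.path) == u.sequence


# -- cleanup properties ----------------------------------------------------


def test_cleanup_is_monotone_and_idempotent(rng):
    reads = shredded_reads(rng, 180, 30, 8) + [
        PeptideRead("dup0", shredded_reads(rng, 180, 30, 8)[0].sequence)
    ]
    reads = [PeptideRead(f"n{i}", r.sequence) for i, r in enumerate(reads)]
    g, _, _ = _graph_from(reads, l=10, n_blocks=3)
    transitive_reduction(g)
    n0, e0 = len(g.nodes), g.n_edges
    remove_bubbles(g, depth=10)
    n1, e1 = len(g.nodes), g.n_edges
    assert n1 <= n0 and e1 <= e0
    remove_bubbles(g, depth=10)
    assert (len(g.nodes), g.n_edges) == (n1, e1)  # fixed point
    trim_tips(g)
    n2, e2 = len(g.nodes), g.n_edges
    assert n2 <= n1 and e2 <= e1
    trim_tips(g)
    assert (len(g.nodes), g.n_edges) == (n2, e2)


def test_block_partition_robustness(rng):
    from peptig.synthetic_data import generate_community, shred_reads

    for seed in range(5):
        comm = generate_community(2, 400, 1, 1.0, seed=seed)
        reads, _ = shred_reads(comm, 33, 8.0, 0.01, seed=seed + 100)
        sets = []
        for nb in (1, 4):
            bs = max(1, (len(reads) + nb - 1) // nb)
            ug = build_unitig_graph(build_blocks(reads, bs), l=10)
            sets.append({u.sequence for u in ug.unitigs})
        assert sets[0] == sets[1]


def test_transitive_reduction_preserves_unitig_spellings(rng):
    reads = shredded_reads(rng, 200, 30, 6)
    blocks = build_blocks(reads, 10_000)
    ov, ct = find_overlaps(blocks, l=10)
    seqs = all_sequences(blocks)
    with_tr = build_graph(ov, ct, seqs)
    transitive_reduction(with_tr)
    remove_bubbles(with_tr)
    trim_tips(with_tr)
    without_tr = build_graph(ov, ct, seqs)
    remove_bubbles(without_tr)
    trim_tips(without_tr)
    # maximal-path spellings survive either way; compare via set inclusion
    spell_tr = {u.sequence for u in collapse_unitigs(with_tr).unitigs}
    joined = "".join(sorted(spell_tr))
    for u in collapse_unitigs(without_tr).unitigs:
        assert any(u.sequence in s or s in u.sequence for s in spell_tr) or u.sequence in joined


def test_polymorphism_retention_two_variants_survive():
    from peptig.synthetic_data import generate_community

    comm = generate_community(1, 300, 1, 1.0, seed=3, copies_per_query=1, query_length=90)
    genome = comm.proteomes["g0"]
    ph = comm.planted_homologs[0]
    variant = genome[: ph.start + 40] + ("A" if genome[ph.start + 40] != "A" else "C") + genome[ph.start + 41 :]
    reads = []
    for i, p in enumerate(range(0, len(genome) - 30 + 1, 5)):
        reads.append(PeptideRead(f"g_{i}", genome[p : p + 30]))
        reads.append(PeptideRead(f"v_{i}", variant[p : p + 30]))
    ug = build_unitig_graph(build_blocks(reads, 10_000), l=10)
    spells = {u.sequence for u in ug.unitigs}
    site_g = genome[ph.start + 35 : ph.start + 46]
    site_v = variant[ph.start + 35 : ph.start + 46]
    assert any(site_g in s for s in spells)
    assert any(site_v in s for s in spells)
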