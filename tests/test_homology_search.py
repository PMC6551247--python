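"""Homolog search: seeding, anchors, candidate paths, banded DP, E-values."""

import math
import random

import pytest

from peptig.alphabet import AA20, blosum62, score_ungapped
from peptig.homology_search import (
    Anchor,
    SeedMatch,
    banded_smith_waterman,
    evalue_of,
    expand_edit_string,
    generate_candidate_paths,
    index_seeds,
    select_anchors,
    ungapped_extend,
)
from peptig.string_graph import UnitigGraph

from conftest import best_diagonal_segment, full_smith_waterman_score


def _random_seq(rng, n):
    return "".join(rng.choice(AA20) for _ in range(n))


# -- seed index ------------------------------------------------------------


def test_minimal_unitig_contributes_exactly_one_seed():
    ug = UnitigGraph.from_sequences({0: "MKVLIT"}, [])
    idx = index_seeds(ug, k=6)
    assert idx.lookup("MKVLIT") == [(0, 0)]
    assert idx.seeds_for("MKVLIT") == [SeedMatch(0, 0, 0, 6)]


def test_windows_with_ambiguous_residue_are_not_indexed():
    ug = UnitigGraph.from_sequences({0: "MKVXITAAGH"}, [])
    idx = index_seeds(ug, k=4)
    assert idx.lookup("MKVX") == []
    assert idx.lookup("ITAA") == [(0, 4)]


def test_seed_lookup_equals_brute_force_window_comparison(rng):
    seqs = {i: _random_seq(rng, rng.randint(6, 60)) for i in range(10)}
    ug = UnitigGraph.from_sequences(seqs, [])
    idx = index_seeds(ug, k=6)
    for _ in range(50):
        query = _random_seq(rng, 20)
        expected = [
            (q, uid, p)
            for q in range(len(query) - 5)
            for uid, s in seqs.items()
            for p in range(len(s) - 5)
            if query[q : q + 6] == s[p : p + 6]
        ]
        got = [(m.query_pos, m.unitig_id, m.unitig_pos) for m in idx.seeds_for(query)]
        assert sorted(got) == sorted(expected)


# -- ungapped extension ----------------------------------------------------


def test_identical_sequences_extend_to_full_self_score(rng):
    seq = _random_seq(rng, 10)
    seed = SeedMatch(2, 2, 0, 6)
    seed = SeedMatch(2, 0, 2, 6)
    anchor = ungapped_extend(seq, seq, seed, threshold=0)
    assert anchor.query_interval == (0, 10) and anchor.unitig_interval == (0, 10)
    assert anchor.ungapped_score == sum(blosum62(c, c) for c in seq)


def test_hostile_flanks_leave_anchor_at_seed():
    # W vs G scores -2; repeated hostile pairs on both sides of the seed
    query = "GGG" + "MKVLIT" + "GGG"
    unitig = "WWW" + "MKVLIT" + "WWW"
    anchor = ungapped_extend(query, unitig, SeedMatch(3, 0, 3, 6), threshold=0)
    assert anchor.query_interval == (3, 9)
    assert anchor.ungapped_score == score_ungapped("MKVLIT", "MKVLIT")


def test_extension_matches_exhaustive_segment_enumeration(rng):
    for _ in range(100):
        n = rng.randint(12, 40)
        query, unitig = _random_seq(rng, n), _random_seq(rng, n)
        # plant a shared 6-mer so the seed is genuine
        pos = rng.randint(0, n - 6)
        core = _random_seq(rng, 6)
        query = query[:pos] + core + query[pos + 6 :]
        unitig = unitig[:pos] + core + unitig[pos + 6 :]
        anchor = ungapped_extend(query, unitig, SeedMatch(pos, 0, pos, 6), threshold=-(10**9), xdrop=None)
        best_score, qiv, uiv = best_diagonal_segment(query, unitig, pos, pos, 6)
        assert anchor.ungapped_score == best_score


def test_anchor_score_reproducible_from_intervals(rng):
    query, unitig = _random_seq(rng, 30), _random_seq(rng, 30)
    core = "MKVLIT"
    query = query[:10] + core + query[16:]
    unitig = unitig[:10] + core + unitig[16:]
    anchor = ungapped_extend(query, unitig, SeedMatch(10, 0, 10, 6), threshold=0)
    qs, qe = anchor.query_interval
    us, ue = anchor.unitig_interval
    assert anchor.ungapped_score == score_ungapped(query[qs:qe], unitig[us:ue])


# -- anchor selection ------------------------------------------------------


def _mk_anchor(uid, score, qpos=0):
    return Anchor(uid, score, (qpos, qpos + 6), (0, 6))


def test_anchor_ordering_and_threshold():
    anchors = [_mk_anchor(0, 12), _mk_anchor(1, 40), _mk_anchor(2, 25)]
    out = select_anchors(anchors, threshold=20)
    assert [a.ungapped_score for a in out] == [40, 25]
    assert select_anchors([], threshold=20) == []


def test_equal_scores_break_ties_deterministically():
    anchors = [_mk_anchor(5, 30, qpos=4), _mk_anchor(2, 30, qpos=9), _mk_anchor(2, 30, qpos=1)]
    out = select_anchors(anchors, threshold=10)
    assert [(a.unitig_id, a.query_interval[0]) for a in out] == [(2, 1), (5, 4)]


# -- candidate paths -------------------------------------------------------


def _branching_graph():
    """Condensed graph: 3->6->9->12->14 spine with 4->12 and 7->12 joins."""
    seqs = {uid: _random_seq(random.Random(uid), 10) for uid in (3, 4, 6, 7, 9, 12, 14)}
    edges = [(3, 6, 0), (6, 9, 0), (9, 12, 0), (4, 12, 0), (7, 12, 0), (12, 14, 0)]
    return UnitigGraph.from_sequences(seqs, edges)


def test_worked_branching_example_with_redundancy_suppression():
    ug = _branching_graph()
    anchors = [
        Anchor(6, 50, (10, 20), (0, 10)),  # higher score: traversed first
        Anchor(12, 40, (10, 20), (0, 10)),
    ]
    paths = generate_candidate_paths(ug, anchors, query_length=30, slack=0.0)
    walks = sorted(tuple(p.unitigs) for p in paths)
    assert walks == [(3, 6, 9), (4, 12, 14), (7, 12, 14)]
    assert (9, 12, 14) not in walks  # unitig 9 already claimed by (3, 6, 9)


def test_single_anchor_linear_chain_yields_one_path():
    seqs = {0: "MKVLITAAGH", 1: "AAGHLKWQER", 2: "WQERSPDNMY"}
    ug = UnitigGraph.from_sequences(seqs, [(0, 1, 4), (1, 2, 4)])
    anchors = [Anchor(1, 30, (6, 12), (0, 6))]
    paths = generate_candidate_paths(ug, anchors, query_length=18, slack=0.0)
    assert [p.unitigs for p in paths] == [[0, 1, 2]]
    assert paths[0].sequence == ug.spell_path([0, 1, 2])


def test_paths_respect_adjacency_and_contain_an_anchor(rng):
    ug = _branching_graph()
    anchors = [Anchor(9, 35, (0, 10), (0, 10))]
    for p in generate_candidate_paths(ug, anchors, query_length=40):
        assert 9 in p.unitigs
        for a, b in zip(p.unitigs, p.unitigs[1:]):
            assert b in ug.out[a]


def test_claiming_is_deterministic():
    ug = _branching_graph()
    anchors = [Anchor(6, 50, (10, 20), (0, 10)), Anchor(12, 40, (10, 20), (0, 10))]
    runs = [
        [tuple(p.unitigs) for p in generate_candidate_paths(ug, anchors, 30, slack=0.0)]
        for _ in range(3)
    ]
    assert runs[0] == runs[1] == runs[2]


# -- banded Smith-Waterman -------------------------------------------------


def _replay_edit(query, path, result):
    qs, qe = result.query_interval
    ps, pe = result.path_interval
    qi, pi = qs, ps
    for count, op in expand_edit_string(result.edit_string):
        for _ in range(count):
            if op == "=":
                assert query[qi] == path[pi]
                qi += 1
                pi += 1
            elif op == "X":
                assert query[qi] != path[pi]
                qi += 1
                pi += 1
            elif op == "I":
                qi += 1
            else:
                pi += 1
    assert (qi, pi) == (qe, pe)


def test_self_alignment_scores_diagonal_sum(rng):
    seq = _random_seq(rng, 25)
    res = banded_smith_waterman(seq, seq, band_width=1)
    assert res.score == sum(blosum62(c, c) for c in seq)
    assert res.edit_string == f"{len(seq)}="
    _replay_edit(seq, seq, res)


def test_full_band_equals_independent_full_matrix_dp(rng):
    for _ in range(150):
        a = _random_seq(rng, rng.randint(5, 35))
        b = _random_seq(rng, rng.randint(5, 35))
        res = banded_smith_waterman(a, b, band_width=len(a) + len(b))
        assert res.score == full_smith_waterman_score(a, b)
        if res.score > 0:
            _replay_edit(a, b, res)


def test_widening_band_is_monotone_non_decreasing(rng):
    for _ in range(20):
        a = _random_seq(rng, 30)
        b = _random_seq(rng, 30)
        scores = [banded_smith_waterman(a, b, w).score for w in (1, 3, 6, 12, 60)]
        assert scores == sorted(scores)
        assert scores[-1] == full_smith_waterman_score(a, b)


def test_disjoint_hostile_sequences_report_no_alignment():
    res = banded_smith_waterman("WWWWWW", "GGGGGG", band_width=12)
    assert res.score == 0 and res.edit_string == ""


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        banded_smith_waterman("", "MKVLIT", 5)


# -- E-values --------------------------------------------------------------


def test_evalue_closed_form_and_monotonicity():
    e = evalue_of(50, 100, 10**6, lam=0.267, k_param=0.041)
    assert e == pytest.approx(0.041 * 100 * 1e6 * math.exp(-0.267 * 50))
    assert evalue_of(60, 100, 10**6) < evalue_of(50, 100, 10**6)
    assert evalue_of(50, 100, 2 * 10**6) == pytest.approx(2 * e)
    assert evalue_of(10_000, 100, 10**6) == pytest.approx(0.0, abs=1e-300)
    with pytest.raises(ValueError):
        evalue_of(10, 0, 100)


# -- end-to-end search -----------------------------------------------------


def test_query_without_shared_kmers_returns_nothing(rng):
    from peptig.homology_search import assemble_homologs

    ug = UnitigGraph.from_sequences({0: "MKVLITAAGHLKWQERSPDN"}, [])
    idx = index_seeds(ug, k=6)
    hits = assemble_homologs("q", "W" * 40, ug, idx, database_residues=1000)
    assert hits == []


def test_planted_query_recovered_in_full(rng):
    from peptig.fm_index import build_blocks
    from peptig.pipeline import run_pipeline
    from peptig.synthetic_data import generate_community, shred_reads

    comm = generate_community(3, 600, 1, 1.0, seed=5)
    reads, _ = shred_reads(comm, 33, 10.0, 0.0, seed=6)
    res = run_pipeline(reads, comm.queries)
    q = comm.queries["q0"]
    assert any(q in c.sequence for c in res.contigs)


def test_divergent_homolog_covered_by_contig_alignment(rng):
    from peptig.pipeline import run_pipeline
    from peptig.synthetic_data import generate_community, shred_reads

    comm = generate_community(4, 800, 1, 0.75, seed=9)
    reads, _ = shred_reads(comm, 33, 10.0, 0.0, seed=10)
    res = run_pipeline(reads, comm.queries)
    assert res.contigs
    best = min(res.contigs, key=lambda c: c.evalue)
    qs, qe = best.alignment.query_interval
    assert (qe - qs) >= 0.8 * len(comm.queries["q0"])
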