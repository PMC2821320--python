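"""Information-preserving graph transformations.

The load-bearing checks compare the exact set of spelled reconstructions
(canonical cyclic words for circular genomes, literal words for linear ones)
before and after each transformation, using the exhaustive oracle.
"""

import pytest

from asmcomplexity import (Genome, KmerGraph, build_graph, path_compress,
                           collapse_trees, split_half_decisions,
                           infer_pigeonhole_paths, convert_nondecision_to_edges,
                           maximal_compress, enumerate_words, random_genome)

TRANSFORMS = [
    ("path_compress", path_compress),
    ("collapse_trees", collapse_trees),
    ("split_half_decisions", split_half_decisions),
    ("infer_pigeonhole_paths", infer_pigeonhole_paths),
    ("maximal_compress", lambda g: maximal_compress(g)[0]),
]


def words_of(graph):
    res = enumerate_words(graph)
    return res.cyclic_words if res.mode == "circuit" else res.distinct_words


class TestPathCompress:
    def test_simple_cycle_collapses_to_self_loop(self):
        g = path_compress(build_graph(Genome("c", "ACGGTA", "circular"), 3))
        assert len(g.nodes) == 1
        (u,) = g.nodes
        assert g.multiplicity(u, u) == 1
        assert len(g.seq(u)) == 6 + 1  # n + k - 2

    def test_parallel_edges_are_consumed(self):
        # AT <-> TA x3 merges into one node with 3 self-loops
        g = path_compress(build_graph(Genome("p", "ATATAT", "circular"), 3))
        assert len(g.nodes) == 1
        (u,) = g.nodes
        assert g.multiplicity(u, u) == 3

    def test_worked_example_is_already_compressed(self, toy_graph):
        g = path_compress(toy_graph)
        assert len(g.nodes) == 3 and g.total_edges() == 7

    def test_trail_endpoint_guard_preserves_words(self):
        # compressing across s/t would corrupt the spelled word
        for seed in range(15):
            genome = random_genome(11, seed + 50, "ACG", topology="linear")
            G = build_graph(genome, 3)
            before = words_of(G)
            assert genome.sequence in before
            assert words_of(path_compress(G)) == before


class TestCollapseTrees:
    def test_rosette_absorbed_with_external_edges(self):
        # circular genome with a tandem triplication: the loop node has one
        # external in/out once compressed, and collapses to a forced spelling
        genome = Genome("t", "ACG" * 3 + "TTCAT", "circular")
        G = build_graph(genome, 3)
        H = collapse_trees(G)
        assert len(H.nodes) == 1
        assert words_of(H) == words_of(G)

    def test_no_leaves_is_identity(self, interleaved):
        G = build_graph(interleaved, 2)
        H = collapse_trees(G)
        assert H.total_edges() == G.total_edges()
        assert len(H.nodes) == len(G.nodes)

    def test_two_copy_repeat_fully_resolves(self):
        # a single interspersed 2-copy repeat is tree-like (figure-eight):
        # the only edge pairing that yields one closed tour is the true one
        G = build_graph(Genome("f8", "AXCRYBZR", "circular", alphabet=None), 2)
        H = collapse_trees(G)
        assert len(H.nodes) == 1
        assert words_of(H) == words_of(G)


class TestSplitHalfDecisions:
    def test_full_decisions_untouched(self, interleaved):
        G = build_graph(interleaved, 2)
        # R and S are full decisions (2 in, 2 out); everything else merges
        H = split_half_decisions(G)
        assert words_of(H) == words_of(G)

    def test_multiplicity_bookkeeping(self):
        # hand-built backward decision: u1 (x2), u2 (x1) -> v -> w (x3);
        # after splitting plus recompression each fan edge keeps its count
        g = KmerGraph(3, "linear")
        u1, u2, v, w = (g.new_node(s) for s in ("AA", "BA", "AC", "CC"))
        g.add_edge(u1, v, 2)
        g.add_edge(u2, v, 1)
        g.add_edge(v, w, 3)
        h = split_half_decisions(g)
        arriving = sorted((h.seq(a)[0], m) for a, b, _, m in h.edge_groups()
                          if b not in (u1, u2))
        assert arriving == [("A", 2), ("B", 1)]
        assert h.total_edges() == 3
        assert "AC" not in {h.seq(u) for u in h.nodes} or len(h.nodes) < 4


class TestPigeonhole:
    def test_forced_path_condition(self):
        # in-edges u x3, x x1; out-edges w x3, y x1: 3 > 4 - 3, so
        # f = 3 + 3 - 4 = 2 traversals of u -> v -> w are forced
        g = KmerGraph(3, "circular")
        u, x, v, w, y = (g.new_node(s) for s in ("AU", "AX", "UV", "VW", "VY"))
        for a, b, m in [(u, v, 3), (x, v, 1), (v, w, 3), (v, y, 1)]:
            g.add_edge(a, b, m)
        g2 = infer_pigeonhole_paths(g)
        assert g2.multiplicity(u, v) == 1
        assert g2.multiplicity(v, w) == 1
        copies = [c for c in g2.nodes if c not in g.nodes]
        assert len(copies) == 1
        (c,) = copies
        assert g2.seq(c) == g2.seq(v)
        assert g2.multiplicity(u, c) == 2 and g2.multiplicity(c, w) == 2
        assert g2.total_edges() == g.total_edges()

    def test_balanced_tie_is_identity(self):
        g = KmerGraph(3, "circular")
        u, x, v, w, y = (g.new_node(s) for s in ("AU", "AX", "UV", "VW", "VY"))
        for a, b, m in [(u, v, 2), (x, v, 2), (v, w, 2), (v, y, 2)]:
            g.add_edge(a, b, m)
        g2 = infer_pigeonhole_paths(g)
        assert sorted(g2.edge_groups()) == sorted(g.edge_groups())

    def test_word_set_unchanged(self):
        for seed in range(20):
            G = build_graph(random_genome(12, seed + 7, "ACG"), 3)
            assert words_of(infer_pigeonhole_paths(G)) == words_of(G)


class TestConvertNondecision:
    def test_surviving_nodes_are_decisions_or_single(self):
        for seed in range(20):
            G = build_graph(random_genome(13, seed, "AC"), 3)
            H, _ = maximal_compress(G)
            if len(H.nodes) > 1:
                for u in H.nodes:
                    assert H.in_degree(u) > 1 and H.out_degree(u) > 1

    def test_labeled_edge_created(self, interleaved):
        G = build_graph(interleaved, 2)
        H = convert_nondecision_to_edges(split_half_decisions(G))
        labels = [lab for *_, lab, _m in
                  [(u, v, lab, m) for u, v, lab, m in H.edge_groups()] if lab]
        assert labels, "conversion should label at least one edge here"
        assert words_of(H) == words_of(G)

    def test_already_only_decisions_is_identity(self, interleaved):
        # after maximal compression only full decisions survive; a second
        # conversion pass has nothing left to do
        G, _ = maximal_compress(build_graph(interleaved, 2))
        H = convert_nondecision_to_edges(G)
        assert sorted(H.edge_groups()) == sorted(G.edge_groups())
        assert set(H.nodes) == set(G.nodes)


class TestMaximalCompress:
    @pytest.mark.parametrize("alpha,length,k", [
        ("AC", 10, 3), ("ACG", 12, 3), ("ACGT", 14, 4), ("AB", 8, 2),
    ])
    def test_word_set_preserved_end_to_end(self, alpha, length, k):
        for seed in range(15):
            G = build_graph(random_genome(length, seed * 3 + 1, alpha), k)
            before = words_of(G)
            for name, fn in TRANSFORMS:
                assert words_of(fn(G)) == before, name

    def test_stage_counts_and_percentages_consistent(self):
        G = build_graph(random_genome(300, 9, "ACGT"), 12)
        H, st = maximal_compress(G)
        assert st.edges_after_conversion == H.total_edges()
        assert st.edges_initial >= st.edges_after_trees >= st.edges_after_conversion
        # percentages recompute from the counts
        assert st.percent_total == pytest.approx(
            100.0 * (st.edges_initial - st.edges_after_conversion) / st.edges_initial)
        assert st.percent_trees == pytest.approx(
            100.0 * (st.edges_initial - st.edges_after_trees) / st.edges_initial)

    def test_single_cycle_genome_terminal_form(self):
        # a repeat-free circular genome ends as one node with one self-loop,
        # whose net length is exactly the genome length
        H, st = maximal_compress(build_graph(Genome("c", "ACGGTA", "circular"), 3))
        assert len(H.nodes) == 1
        (u,) = H.nodes
        assert H.multiplicity(u, u) == 1
        assert len(H.seq(u)) - (3 - 2) == 6

    def test_eulerian_balance_preserved(self):
        for seed in range(10):
            G = build_graph(random_genome(200, seed, "ACGT"), 8)
            for name, fn in TRANSFORMS:
                fn(G).balance()  # raises if violated
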