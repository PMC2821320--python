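"""Gene reconstructibility classification."""

import numpy as np
import pytest

from asmcomplexity import (Genome, GeneAnnotation, prepare_recon_graph,
                           genome_decomposition, locate_start_node,
                           is_reconstructible, summarize_reconstructibility,
                           analyze_genes, SimSpec, GeneSpec, RepeatFamily,
                           generate_genome, enumerate_words, build_graph)


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def repeat3_fixture():
    """Circular genome UA + R + UB + R + UC + R with a 3-copy repeat R.

    Three copies interleave as a triangle of cycles, so R survives tree
    collapse as a full decision node (3 in / 3 out).
    """
    rng = np.random.default_rng(42)
    R = _rand(rng, 40)
    # pin distinct first/last flank bases so the only shared k-mers are R's
    # own: otherwise two copies sharing a chance boundary base create extra
    # (legitimate) junction decision nodes
    UA = "A" + _rand(rng, 118) + "T"
    UB = "C" + _rand(rng, 128) + "A"
    UC = "G" + _rand(rng, 108) + "C"
    genome = Genome("fix", UA + R + UB + R + UC + R, "circular")
    return genome, R, UA, UB, UC


class TestPrepareReconGraph:
    def test_repeat_free_genome_single_node(self):
        genome, _, _ = generate_genome(SimSpec(300, 1))
        g = prepare_recon_graph(genome, 15)
        assert len(g.nodes) == 1

    def test_repeat_decision_node_retained(self, repeat3_fixture):
        genome, R, *_ = repeat3_fixture
        g = prepare_recon_graph(genome, 21)
        decisions = [u for u in g.nodes if g.in_degree(u) > 1]
        assert len(decisions) == 1
        (d,) = decisions
        assert g.in_degree(d) == 3 and g.out_degree(d) == 3
        assert R in g.seq(d)

    def test_word_set_preserved(self):
        for seed in range(10):
            genome = Genome("r", "".join(
                "AC"[i] for i in np.random.default_rng(seed).integers(0, 2, 12)),
                "circular", alphabet="AC")
            G = build_graph(genome, 3)
            H = prepare_recon_graph(genome, 3)
            assert enumerate_words(H).cyclic_words == enumerate_words(G).cyclic_words


class TestLocateStartNode:
    def test_offsets_across_whole_genome(self, repeat3_fixture):
        genome, *_ = repeat3_fixture
        g = prepare_recon_graph(genome, 21)
        n = len(genome)
        decomp = genome_decomposition(g, genome)
        # every position maps to exactly one decomposition element's net span
        o = g.k - 2
        covered = sorted((occ + i) % n for u, occ in decomp
                         for i in range(len(g.seq(u)) - o))
        assert covered == list(range(n))
        for p0 in (0, 5, n - 1, len(genome) // 2):
            gene = GeneAnnotation("g", p0 + 1, p0 + 1, "+")
            u, off = locate_start_node(g, genome, gene)
            occs = g.nodes[u].occurrences
            assert any((p0 - occ) % n == off for occ in occs)

    def test_downstream_node_chosen_in_overlap(self, repeat3_fixture):
        genome, *_ = repeat3_fixture
        g = prepare_recon_graph(genome, 21)
        decomp = genome_decomposition(g, genome)
        n = len(genome)
        o = g.k - 2
        u0, occ0 = decomp[0]
        u1, occ1 = decomp[1 % len(decomp)]
        # a base inside the k-2 overlap belongs to the downstream node
        p = occ1 % n
        gene = GeneAnnotation("g", p + 1, p + 1, "+")
        u, off = locate_start_node(g, genome, gene)
        assert (u, off) == (u1, 0)


class TestIsReconstructible:
    def test_gene_with_repeat_copy_not_reconstructible(self, repeat3_fixture):
        genome, R, UA, UB, UC = repeat3_fixture
        # spans UA tail, all of R, UB head
        gene = GeneAnnotation("bad", len(UA) - 30 + 1, len(UA) + len(R) + 30, "+",
                              "transposase")
        graph = prepare_recon_graph(genome, 21)
        ok, outcome = is_reconstructible(graph, genome, gene)
        assert not ok
        assert outcome.terminated_at_forward == [True]
        assert outcome.passed_backward == [True]

    def test_gene_adjacent_to_repeat_is_reconstructible(self, repeat3_fixture):
        genome, R, UA, UB, UC = repeat3_fixture
        s2 = len(UA) + len(R) + 20  # inside UB, downstream of a repeat copy
        gene = GeneAnnotation("good", s2 + 1, s2 + 60, "+")
        graph = prepare_recon_graph(genome, 21)
        ok, outcome = is_reconstructible(graph, genome, gene)
        assert ok

    def test_gene_inside_single_node_region(self, repeat3_fixture):
        genome, R, UA, UB, UC = repeat3_fixture
        graph = prepare_recon_graph(genome, 21)
        gene = GeneAnnotation("inUC", len(UA) + len(R) + len(UB) + len(R) + 10,
                              len(UA) + len(R) + len(UB) + len(R) + 80, "+")
        ok, _ = is_reconstructible(graph, genome, gene)
        assert ok

    def test_repeat_free_genome_all_genes_all_k(self):
        genome, annots, _ = generate_genome(SimSpec(
            400, 5, (), (GeneSpec(10, 90), GeneSpec(380, 60),
                         GeneSpec(200, 120, "-"))))
        for k in (13, 15, 25, 40):
            report, _ = analyze_genes(genome, annots, k)
            assert report.fraction_reconstructible == 100.0

    def test_rotation_invariance(self, repeat3_fixture):
        genome, R, UA, UB, UC = repeat3_fixture
        n = len(genome)
        shift = 57
        rotated = Genome("rot", genome.sequence[shift:] + genome.sequence[:shift],
                         "circular")
        for start0, length in [(len(UA) - 30, len(R) + 60), (len(UA) + len(R) + 20, 60)]:
            gene = GeneAnnotation("g", start0 + 1, start0 + length, "+")
            rs = (start0 - shift) % n
            rgene = GeneAnnotation("g", rs + 1, (rs + length - 1) % n + 1, "+")
            ok1, _ = is_reconstructible(prepare_recon_graph(genome, 21), genome, gene)
            ok2, _ = is_reconstructible(prepare_recon_graph(rotated, 21), rotated, rgene)
            assert ok1 == ok2


class TestSummarize:
    def test_fraction(self):
        flags = {f"g{i}": (i != 0, "") for i in range(10)}
        annots = [GeneAnnotation(f"g{i}", 1 + i, 1 + i) for i in range(10)]
        rep = summarize_reconstructibility(flags, annots)
        assert rep.fraction_reconstructible == 90.0

    def test_keyword_tallies_exclude_hypothetical(self):
        annots = [
            GeneAnnotation("a", 1, 9, "+", "IS66 Transposase subunit"),
            GeneAnnotation("b", 10, 19, "+", "hypothetical protein"),
            GeneAnnotation("c", 20, 29, "+", "prophage integrase"),
            GeneAnnotation("d", 30, 39, "+", "ribosomal protein L1"),
        ]
        flags = {a.gene_id: (False, "") for a in annots}
        rep = summarize_reconstructibility(flags, annots)
        assert rep.keyword_tallies["transpos"] == 1
        assert rep.keyword_tallies["integrase"] == 1
        assert rep.keyword_tallies["phage"] == 1  # "prophage" contains it
        assert rep.fraction_reconstructible == 0.0

    def test_empty_annotation_list(self):
        rep = summarize_reconstructibility({}, [])
        assert rep.fraction_reconstructible is None
        assert rep.n_genes == 0
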