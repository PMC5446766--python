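"""FF-Median instance construction: scores, candidates, conflicts, weights."""

import pytest

from ffmedian3.genomes_io import Genome
from ffmedian3.median_model import (
    adjacency_score,
    build_instance,
    conflicting,
    enumerate_candidates,
    median_gene_score,
)
from ffmedian3.synth import random_similarity_triple

from conftest import identity_triple, make_graph


class TestScores:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5), (1.0, 0.0, 0.0)],
    )
    def test_adjacency_score_is_geometric_mean(self, s1, s2, expected):
        genomes, graph = identity_triple(2)
        G, H, _ = genomes
        sigma = {("g0", "h0"): s1, ("g1", "h1"): s2}

        def sig(x, y):
            return sigma.get(tuple(sorted((x.id, y.id))), 0.0)

        got = adjacency_score(
            G.gene("g0").head, H.gene("h0").head,
            G.gene("g1").tail, H.gene("h1").tail,
            sig,
        )
        assert got == pytest.approx(expected)

    def test_telomere_pairs_score_one(self):
        genomes, _ = identity_triple(1)
        G, H, _ = genomes
        tG, tH = G.gene("c1:TL"), H.gene("c1:TL")
        got = adjacency_score(
            tG.extremities[0], tH.extremities[0],
            G.gene("g0").tail, H.gene("h0").tail,
            lambda x, y: 1.0,
        )
        assert got == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "sims,expected",
        [((1, 1, 1), 1.0), ((0.8, 0.8, 0.8), 0.8), ((1, 1, 0), 0.0)],
    )
    def test_median_gene_score_is_cube_root(self, sims, expected):
        assert median_gene_score(*sims) == pytest.approx(expected)


class TestCandidates:
    def test_worked_graph_yields_exactly_the_four_triangles(
        self, fig_similarity_graph
    ):
        _, graph = fig_similarity_graph
        cands = enumerate_candidates(graph)
        assert [c.key for c in cands] == [
            ("g1", "h1", "i2"),
            ("g2", "h2", "i1"),
            ("g3", "h3", "i2"),
            ("g4", "h3", "i3"),
        ]

    def test_conflicts_are_shared_extant_genes(self, fig_similarity_graph):
        _, graph = fig_similarity_graph
        m1, m2, m3, m4 = enumerate_candidates(graph)
        assert conflicting(m1, m3)  # share i2
        assert conflicting(m3, m4)  # share h3
        assert not conflicting(m1, m2)
        assert not conflicting(m1, m1)

    def test_candidates_match_exhaustive_triple_loop(self):
        for seed in range(5):
            genomes, graph = random_similarity_triple(seed, n_genes=4)
            G, H, I = genomes
            expected = {
                (g.id, h.id, i.id)
                for g in G.non_telomeric_genes()
                for h in H.non_telomeric_genes()
                for i in I.non_telomeric_genes()
                if graph.sigma(g, h) > 0
                and graph.sigma(g, i) > 0
                and graph.sigma(h, i) > 0
            }
            assert {c.key for c in enumerate_candidates(graph)} == expected

    def test_shared_pair_makes_conflicting_candidates(self):
        G = Genome.from_orders("G", [("c1", "linear", [(1, "g1")])])
        H = Genome.from_orders("H", [("c1", "linear", [(1, "h1")])])
        I = Genome.from_orders("I", [("c1", "linear", [(1, "i1"), (1, "i2")])])
        graph = make_graph(
            (G, H, I),
            {("g1", "h1"): 1, ("g1", "i1"): 1, ("h1", "i1"): 1,
             ("g1", "i2"): 1, ("h1", "i2"): 1},
        )
        cands = enumerate_candidates(graph)
        assert len(cands) == 2
        assert conflicting(*cands)


class TestConservedAdjacencies:
    def test_triple_conservation_with_unit_sigma_weighs_three(self):
        _, graph = identity_triple(2)
        instance = build_instance(graph, include_telomeres=False)
        [adj] = instance.adjacencies
        assert adj.weight == pytest.approx(3.0)
        assert adj.support == frozenset({"G", "H", "I"})

    def test_sixth_root_weighting(self):
        _, graph = identity_triple(2, sigma=0.5)
        instance = build_instance(graph, include_telomeres=False)
        [adj] = instance.adjacencies
        # conserved in all three genomes: w = 3 * (0.5^6)^(1/6)
        assert adj.weight == pytest.approx(3 * (0.5 ** 6) ** (1 / 6))

    def test_single_genome_conservation_weighs_one(self):
        G = Genome.from_orders("G", [("c1", "linear", [(1, "ga"), (1, "gb")])])
        H = Genome.from_orders("H", [("c1", "linear", [(1, "hb"), (1, "ha")])])
        I = Genome.from_orders("I", [("c1", "linear", [(1, "ib"), (1, "ia")])])
        edges = {}
        for x in "ab":
            for p, q in (("g", "h"), ("g", "i"), ("h", "i")):
                edges[(f"{p}{x}", f"{q}{x}")] = 1.0
        graph = make_graph((G, H, I), edges)
        instance = build_instance(graph, include_telomeres=False)
        # (a, b) adjacent only in G; (b, a) adjacent in H and I
        weights = sorted(adj.weight for adj in instance.adjacencies)
        assert weights == pytest.approx([1.0, 2.0])

    def test_no_adjacency_pairs_conflicting_candidates(self):
        for seed in range(10):
            _, graph = random_similarity_triple(seed, n_genes=5)
            instance = build_instance(graph)
            for adj in instance.adjacencies:
                m1, m2 = adj.candidates
                assert not conflicting(m1, m2)

    def test_weights_match_independent_recomputation(self):
        from ffmedian3.oracle import _independent_weight

        for seed in range(10):
            _, graph = random_similarity_triple(seed, n_genes=5)
            instance = build_instance(graph)
            for adj in instance.adjacencies:
                assert adj.weight == pytest.approx(
                    _independent_weight(adj, graph, instance.genomes)
                )

    def test_unsupported_genes_are_discarded_by_default(self):
        # 'skip' interrupts the (a, b) adjacency in G only; discarding genes
        # outside every 3-clique restores it, conserved in all three genomes
        G = Genome.from_orders(
            "G", [("c1", "linear", [(1, "ga"), (1, "gskip"), (1, "gb")])]
        )
        H = Genome.from_orders("H", [("c1", "linear", [(1, "ha"), (1, "hb")])])
        I = Genome.from_orders("I", [("c1", "linear", [(1, "ia"), (1, "ib")])])
        edges = {}
        for x in "ab":
            for p, q in (("g", "h"), ("g", "i"), ("h", "i")):
                edges[(f"{p}{x}", f"{q}{x}")] = 1.0
        graph = make_graph((G, H, I), edges)
        filtered = build_instance(graph, include_telomeres=False)
        [adj] = filtered.adjacencies
        assert adj.support == frozenset({"G", "H", "I"})
        kept = build_instance(graph, keep_unsupported=True, include_telomeres=False)
        [adj_kept] = kept.adjacencies
        assert adj_kept.support == frozenset({"H", "I"})
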