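"""Similarity graph construction: BLAST parsing, stringency filter, RRBS."""

import pytest
from hypothesis import given, settings, strategies as st

from ffmedian3.simgraph import (
    BlastHit,
    SimilarityError,
    SimilarityGraph,
    read_blast_tab,
    read_sigma_table,
    rrbs_weights,
    stringency_filter,
    write_sigma_table,
)

from conftest import identity_triple


def blast_line(q, s, bit):
    return "\t".join([q, s] + ["0"] * 9 + [str(bit)])


class TestBlastReader:
    def test_parses_query_subject_bitscore(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(blast_line("g1", "h1", 100.0) + "\n")
        assert read_blast_tab(p) == [
            BlastHit("g1", "h1", 100.0, ("0",) * 9)
        ]

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert read_blast_tab(p) == []

    def test_short_line_is_an_error_with_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(blast_line("g1", "h1", 10) + "\n" + "a\tb\tc\td\te\n")
        with pytest.raises(SimilarityError, match=":2"):
            read_blast_tab(p)


GENOME_OF = {"g1": "G", "g2": "G", "h": "H"}


class TestStringencyFilter:
    def test_f_zero_keeps_all_inter_genome_hits(self):
        hits = [BlastHit("h", "g1", 100), BlastHit("h", "g2", 1)]
        kept = stringency_filter(hits, 0.0, GENOME_OF)
        assert len(kept) == 2

    def test_weak_competitor_hit_dropped_at_half(self):
        # h's best hit into genome G scores 100, so the hit from g2 back to h
        # needs at least 0.5 * 100 and fails with 49
        hits = [
            BlastHit("h", "g1", 100), BlastHit("h", "g2", 49),
            BlastHit("g1", "h", 100), BlastHit("g2", "h", 49),
        ]
        kept = stringency_filter(hits, 0.5, GENOME_OF)
        assert BlastHit("g2", "h", 49) not in kept
        assert len(kept) == 3

    def test_unassigned_gene_is_an_error(self):
        with pytest.raises(SimilarityError, match="mystery"):
            stringency_filter([BlastHit("mystery", "g1", 5)], 0.5, GENOME_OF)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["g1", "g2", "h"]),
                st.sampled_from(["g1", "g2", "h"]),
                st.floats(0.1, 100),
            ),
            max_size=15,
        ),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_filter_monotone_in_f(self, raw, f1, f2):
        f1, f2 = min(f1, f2), max(f1, f2)
        hits = [BlastHit(q, s, b) for q, s, b in raw]
        strict = {(h.query, h.subject, h.bitscore)
                  for h in stringency_filter(hits, f2, GENOME_OF)}
        loose = {(h.query, h.subject, h.bitscore)
                 for h in stringency_filter(hits, f1, GENOME_OF)}
        assert strict <= loose


class TestRRBS:
    def triple(self):
        genomes, _ = identity_triple(1)
        return genomes

    def test_identical_sequences_give_sigma_one(self):
        genomes = self.triple()
        hits = [
            BlastHit("g0", "h0", 100), BlastHit("h0", "g0", 100),
            BlastHit("g0", "g0", 100), BlastHit("h0", "h0", 100),
        ]
        graph = rrbs_weights(hits[:2], hits, genomes)
        G, H, _ = genomes
        assert graph.sigma(G.gene("g0"), H.gene("h0")) == pytest.approx(1.0)

    def test_half_scores_give_sigma_half(self):
        genomes = self.triple()
        hits_all = [
            BlastHit("g0", "h0", 50), BlastHit("h0", "g0", 50),
            BlastHit("g0", "g0", 100), BlastHit("h0", "h0", 100),
        ]
        graph = rrbs_weights(hits_all[:2], hits_all, genomes)
        G, H, _ = genomes
        assert graph.sigma(G.gene("g0"), H.gene("h0")) == pytest.approx(0.5)

    def test_single_direction_fallback(self):
        genomes = self.triple()
        hits_all = [
            BlastHit("g0", "h0", 40),
            BlastHit("g0", "g0", 100), BlastHit("h0", "h0", 100),
        ]
        graph = rrbs_weights(hits_all[:1], hits_all, genomes)
        G, H, _ = genomes
        assert graph.sigma(G.gene("g0"), H.gene("h0")) == pytest.approx(0.4)

    def test_missing_self_hit_is_an_error_naming_the_gene(self):
        genomes = self.triple()
        hits = [BlastHit("g0", "h0", 50), BlastHit("g0", "g0", 100)]
        with pytest.raises(SimilarityError, match="h0"):
            rrbs_weights(hits[:1], hits, genomes)


class TestSigmaTable:
    def test_round_trip(self, tmp_path):
        genomes, graph = identity_triple(2, sigma=0.7)
        p = tmp_path / "sigma.tsv"
        write_sigma_table(graph, p)
        again = read_sigma_table(p, genomes)
        assert again.edges() == graph.edges()

    def test_non_positive_sigma_is_an_error(self, tmp_path):
        genomes, _ = identity_triple(1)
        p = tmp_path / "sigma.tsv"
        p.write_text("g0\th0\t0.0\n")
        with pytest.raises(SimilarityError, match="non-positive"):
            read_sigma_table(p, genomes)

    def test_unknown_gene_is_an_error(self, tmp_path):
        genomes, _ = identity_triple(1)
        p = tmp_path / "sigma.tsv"
        p.write_text("g0\tnope\t0.5\n")
        with pytest.raises(SimilarityError, match="nope"):
            read_sigma_table(p, genomes)


class TestGraphInvariants:
    def test_rejects_intra_genome_edges(self):
        genomes, _ = identity_triple(2)
        G = genomes[0]
        with pytest.raises(SimilarityError, match="intra-genome"):
            SimilarityGraph(
                genomes, {frozenset({G.gene("g0"), G.gene("g1")}): 0.5}
            )

    def test_rejects_telomere_edges(self):
        genomes, _ = identity_triple(1)
        G, H, _ = genomes
        with pytest.raises(SimilarityError, match="telomere"):
            SimilarityGraph(
                genomes,
                {frozenset({G.gene("c1:TL"), H.gene("h0")}): 0.5},
            )
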