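"""Shared fixtures: small hand-built genome triples and similarity graphs."""

import pytest

from ffmedian3.genomes_io import Genome
from ffmedian3.simgraph import SimilarityGraph


def make_graph(genomes, edges):
    """Build a SimilarityGraph from {(gene_id, gene_id): sigma} by id lookup."""
    by_id = {g.id: g for genome in genomes for g in genome.non_telomeric_genes()}
    weights = {
        frozenset({by_id[a], by_id[b]}): s for (a, b), s in edges.items()
    }
    return SimilarityGraph(tuple(genomes), weights)


def identity_triple(n=2, sigma=1.0, topology="linear"):
    """Three identical genomes of n genes with a perfect 3-clique per gene."""
    genomes = tuple(
        Genome.from_orders(
            gid, [("c1", topology, [(1, f"{gid.lower()}{k}") for k in range(n)])]
        )
        for gid in ("G", "H", "I")
    )
    edges = {}
    for k in range(n):
        for a, b in (("g", "h"), ("g", "i"), ("h", "i")):
            edges[(f"{a}{k}", f"{b}{k}")] = sigma
    return genomes, make_graph(genomes, edges)


@pytest.fixture
def two_gene_identity():
    return identity_triple(2)


@pytest.fixture
def fig_similarity_graph():
    """The worked four-candidate similarity graph: candidates
    m1=(g1,h1,i2), m2=(g2,h2,i1), m3=(g3,h3,i2), m4=(g4,h3,i3); m1/m3 share
    i2 and m3/m4 share h3."""
    G = Genome.from_orders("G", [("c1", "linear", [(1, f"g{k}") for k in (1, 2, 3, 4)])])
    H = Genome.from_orders("H", [("c1", "linear", [(1, f"h{k}") for k in (1, 2, 3)])])
    I = Genome.from_orders("I", [("c1", "linear", [(1, f"i{k}") for k in (1, 2, 3)])])
    triples = [
        ("g1", "h1", "i2"),
        ("g2", "h2", "i1"),
        ("g3", "h3", "i2"),
        ("g4", "h3", "i3"),
    ]
    edges = {}
    for g, h, i in triples:
        edges[(g, h)] = 1.0
        edges[(g, i)] = 1.0
        edges[(h, i)] = 1.0
    # a stray edge with no third mate must not create a candidate
    edges[("g2", "h1")] = 0.5
    return (G, H, I), make_graph((G, H, I), edges)


@pytest.fixture
def duplication_scenario():
    """Duplication/deletion scenario: the ancestral order 'a b c' survives in
    G and H; in I a displaced extra copy a2 precedes c, so one-genome
    adjacencies (b, a2) and (a2, c) compete with the conserved (a, b) and
    (b, c)."""
    G = Genome.from_orders("G", [("c1", "linear", [(1, "ga"), (1, "gb"), (1, "gc")])])
    H = Genome.from_orders("H", [("c1", "linear", [(1, "ha"), (1, "hb"), (1, "hc")])])
    I = Genome.from_orders(
        "I", [("c1", "linear", [(1, "ia"), (1, "ib"), (1, "ia2"), (1, "ic")])]
    )
    edges = {}
    for x in "abc":
        for p, q in (("g", "h"), ("g", "i"), ("h", "i")):
            edges[(f"{p}{x}", f"{q}{x}")] = 1.0
    # the displaced copy is similar to the a-family in all genomes
    edges[("ga", "ia2")] = 1.0
    edges[("ha", "ia2")] = 1.0
    return (G, H, I), make_graph((G, H, I), edges)
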