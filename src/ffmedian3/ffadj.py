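"""Exact ILP for family-free adjacencies on three genomes (FFAdj-3G).

A *partial 3-matching* M in the tripartite similarity graph B = (G, H, I, E)
is an edge subset whose connected components contain at most one gene per
genome (the seven valid component shapes are: a single edge between any of
the three genome pairs, a two-edge path centred on any of the three genomes,
and a full triangle).  M induces subgenomes whose adjacency sets may join
genes that were not immediate neighbours, as long as all skipped genes are
unmatched.  The objective trades conserved adjacencies against similarity:

    F_alpha(M) = alpha * sum s(x1^a, y1^a, x2^b, y2^b)  over conserved
                 adjacency pairs of M-induced subgenomes
               + (1 - alpha) * sum sigma(x, y)           over edges of M.

The ILP uses binary variables c(x,y) per similarity edge, d(x) per gene, and
e(...) per candidate conserved-adjacency quadruple:

* (C.01) per gene and per other genome, at most one incident saturated edge,
  and d(x) >= c(x, y);
* (C.02) for every edge pair {g,h}, {g,i} into two different genomes, the
  sums c(g,h) + c(g,i) + sum_{i' != i} c(h,i') and
  c(g,h) + c(g,i) + sum_{h' != h} c(i,h') are each at most 2 (the edge
  {h,i} itself is not part of these sums), which excludes exactly the edge
  combinations violating the partial 3-matching property;
* (C.03) e <= c for both edges of the quadruple, and e + d(z) <= 1 for every
  gene z strictly between the two extremities in either genome.

Candidate adjacency sets A*(X) are capped at a configurable number of
skipped genes (``gap_limit``); the full union over all subgenomes grows
quadratically and explodes the number of conflicting conserved adjacencies,
so a small cap keeps exact solving tractable while gap 0 recovers A(X).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .genomes_io import Extremity, Gene, Genome, HEAD, LINEAR, TAIL
from .median_solver import ILPModel, solve_milp
from .oracle import score_partial_matching  # shared audit; oracle owns the scan
from .simgraph import SimilarityGraph


@dataclass(frozen=True)
class GapAdjacency:
    """A candidate adjacency of some subgenome of X: two extremities that
    face each other with ``gap`` skippable genes strictly in between."""

    ends: frozenset  # of Extremity
    gap: int
    between: frozenset  # genes strictly between (non-telomeric)


def _left(gene: Gene, sign: int) -> Extremity:
    return Extremity(gene, TAIL if sign > 0 else HEAD)


def _right(gene: Gene, sign: int) -> Extremity:
    return Extremity(gene, HEAD if sign > 0 else TAIL)


def enumerate_gap_adjacencies(X: Genome, gap_limit: int) -> list[GapAdjacency]:
    """A*(X) capped at ``gap_limit`` skipped genes; gap 0 recovers A(X)."""
    out: dict[frozenset, GapAdjacency] = {}

    def add(e1: Extremity, e2: Extremity, between: tuple[Gene, ...]) -> None:
        ends = frozenset({e1, e2})
        if len(ends) < 2:
            return
        prev = out.get(ends)
        if prev is None or len(between) < prev.gap:
            out[ends] = GapAdjacency(ends, len(between), frozenset(between))

    for chrom in X.chromosomes:
        order = list(chrom.order)
        n = len(order)
        if chrom.topology == LINEAR:
            tl = X.gene(f"{chrom.name}:TL")
            tr = X.gene(f"{chrom.name}:TR")
            seq: list[tuple[Gene, int]] = [(tl, 1)] + order + [(tr, 1)]
            rights = [
                e.extremities[0] if e.is_telomere else _right(e, s)
                for e, s in seq
            ]
            lefts = [
                e.extremities[0] if e.is_telomere else _left(e, s)
                for e, s in seq
            ]
            for i in range(len(seq)):
                for j in range(i + 1, len(seq)):
                    between = tuple(g for g, _s in seq[i + 1 : j])
                    if len(between) > gap_limit:
                        break
                    add(rights[i], lefts[j], between)
        else:  # circular
            for i in range(n):
                for d in range(1, n):
                    j = (i + d) % n
                    between = tuple(order[(i + k) % n][0] for k in range(1, d))
                    if len(between) > gap_limit:
                        break
                    add(_right(*order[i]), _left(*order[j]), between)

    return sorted(
        out.values(),
        key=lambda a: sorted((e.gene.id, e.side) for e in a.ends),
    )


@dataclass
class FFAdjModel:
    """A built FFAdj-3G ILP together with its variable registry."""

    model: ILPModel
    edges: list[tuple[Gene, Gene]]  # column order of the c variables
    genes: list[Gene]  # column order of the d variables
    quads: list[tuple]  # e variables: ((x1,a,y1), (x2,b,y2), score)
    alpha: float
    gap_limit: int
    graph: SimilarityGraph


def build_ffadj_ilp(
    graph: SimilarityGraph,
    alpha: float,
    gap_limit: int = 2,
    fixed_edges: tuple = (),
) -> FFAdjModel:
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    genomes = graph.genomes
    edges = [(x, y) for x, y, _s in graph.edges()]
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}
    genes = sorted({g for e in edges for g in e})
    gene_index = {g: k for k, g in enumerate(genes)}
    ne, ng = len(edges), len(genes)

    gap_adjs = {X.id: enumerate_gap_adjacencies(X, gap_limit) for X in genomes}
    gap_index = {
        X.id: {
            frozenset((e.gene, e.side) for e in a.ends): a
            for a in gap_adjs[X.id]
        }
        for X in genomes
    }

    # enumerate e-variable quadruples
    quads: dict[frozenset, tuple] = {}
    for X, Y in itertools.combinations(genomes, 2):
        for adjX in gap_adjs[X.id]:
            e1, e2 = sorted(adjX.ends, key=lambda e: (e.gene.id, e.side))
            if e1.gene.is_telomere or e2.gene.is_telomere:
                continue
            (x1, a), (x2, b) = (e1.gene, e1.side), (e2.gene, e2.side)
            for y1 in graph.neighbours(x1, Y.id):
                for y2 in graph.neighbours(x2, Y.id):
                    if y1 == y2:
                        continue
                    adjY = gap_index[Y.id].get(frozenset({(y1, a), (y2, b)}))
                    if adjY is None:
                        continue
                    key = frozenset({(x1, a, y1), (x2, b, y2)})
                    if key in quads:
                        continue
                    score = math.sqrt(graph.sigma(x1, y1) * graph.sigma(x2, y2))
                    quads[key] = (
                        (x1, a, y1),
                        (x2, b, y2),
                        score,
                        adjX.between,
                        adjY.between,
                    )
    quad_list = [quads[k] for k in sorted(quads, key=lambda k: sorted(
        (t[0].id, t[1], t[2].id) for t in k))]
    nq = len(quad_list)

    n = ne + ng + nq
    objective = np.zeros(n)
    lower = np.zeros(n)
    var_names = (
        [f"c_{x.id}_{y.id}" for x, y in edges]
        + [f"d_{g.genome_id}_{g.id}" for g in genes]
        + [f"e_{k}" for k in range(nq)]
    )
    rows: list[tuple[list[int], list[float], float]] = []

    for k, (x, y) in enumerate(edges):
        objective[k] = (1 - alpha) * graph.sigma(x, y)
        # d(x) >= c(x, y) for both endpoints
        rows.append(([k, ne + gene_index[x]], [1.0, -1.0], 0.0))
        rows.append(([k, ne + gene_index[y]], [1.0, -1.0], 0.0))

    # C.01: per gene and per other genome, at most one saturated edge
    for g in genes:
        for Y in genomes:
            if Y.id == g.genome_id:
                continue
            cols = [
                edge_index[frozenset({g, y})] for y in graph.neighbours(g, Y.id)
            ]
            if len(cols) >= 2:
                rows.append((sorted(cols), [1.0] * len(cols), 1.0))

    # C.02: edge pairs sharing a gene, into two different genomes
    for g in genes:
        others = [Y for Y in genomes if Y.id != g.genome_id]
        Y1, Y2 = others
        for h in graph.neighbours(g, Y1.id):
            for i in graph.neighbours(g, Y2.id):
                c_gh = edge_index[frozenset({g, h})]
                c_gi = edge_index[frozenset({g, i})]
                cols1 = [c_gh, c_gi] + [
                    edge_index[frozenset({h, i2})]
                    for i2 in graph.neighbours(h, Y2.id)
                    if i2 != i
                ]
                if len(cols1) > 2:
                    rows.append((sorted(cols1), [1.0] * len(cols1), 2.0))
                cols2 = [c_gh, c_gi] + [
                    edge_index[frozenset({i, h2})]
                    for h2 in graph.neighbours(i, Y1.id)
                    if h2 != h
                ]
                if len(cols2) > 2:
                    rows.append((sorted(cols2), [1.0] * len(cols2), 2.0))

    # C.03: conserved adjacencies need both edges saturated and no matched
    # gene strictly in between
    for q, (end1, end2, score, betweenX, betweenY) in enumerate(quad_list):
        col = ne + ng + q
        objective[col] = alpha * score
        (x1, _a, y1), (x2, _b, y2) = end1, end2
        rows.append(([col, edge_index[frozenset({x1, y1})]], [1.0, -1.0], 0.0))
        rows.append(([col, edge_index[frozenset({x2, y2})]], [1.0, -1.0], 0.0))
        for z in sorted(betweenX | betweenY):
            zi = gene_index.get(z)
            if zi is not None:  # genes without similarity edges are never matched
                rows.append(([col, ne + zi], [1.0, 1.0], 1.0))

    for e in fixed_edges:
        k = edge_index.get(frozenset(e))
        if k is None:
            raise ValueError(f"fixed edge {e!r} is not an edge of the graph")
        lower[k] = 1.0

    model = ILPModel(
        var_names,
        objective,
        rows,
        lower,
        meta={
            "kind": "ffadj-3g",
            "n_edges": ne,
            "n_genes": ng,
            "n_quads": nq,
            "alpha": alpha,
            "gap_limit": gap_limit,
        },
    )
    return FFAdjModel(model, edges, genes, quad_list, alpha, gap_limit, graph)


# ---------------------------------------------------------------------------
# solution handling
# ---------------------------------------------------------------------------

#: the seven valid component shapes of a partial 3-matching, keyed by the
#: sorted tuple of genome ids touched by each edge of the component
def component_type(component_edges: list[tuple[Gene, Gene]]) -> str:
    pairs = sorted(
        "".join(sorted((x.genome_id, y.genome_id))) for x, y in component_edges
    )
    if len(pairs) == 1:
        return f"edge:{pairs[0]}"
    if len(pairs) == 2:
        shared = set.intersection(
            *[{x.genome_id, y.genome_id} for x, y in component_edges]
        )
        return f"path:{''.join(sorted(shared))}"
    if len(pairs) == 3:
        return "triangle"
    raise AssertionError(f"invalid component with {len(pairs)} edges")


@dataclass
class PartialMatching:
    """A solved partial 3-matching with its induced score."""

    edges: list[tuple[Gene, Gene]]
    components: list[list[Gene]]
    objective: float  # re-audited F_alpha
    ilp_objective: float
    status: str
    conserved: list[tuple] = field(default_factory=list)
    model_stats: dict = field(default_factory=dict)

    def component_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        comp_of: dict[Gene, int] = {}
        for k, comp in enumerate(self.components):
            for g in comp:
                comp_of[g] = k
        edges_by_comp: dict[int, list] = {}
        for x, y in self.edges:
            edges_by_comp.setdefault(comp_of[x], []).append((x, y))
        for comp_edges in edges_by_comp.values():
            t = component_type(comp_edges)
            census[t] = census.get(t, 0) + 1
        return census

    def validate(self) -> None:
        comp_of: dict[Gene, set[str]] = {}
        for comp in self.components:
            seen: set[str] = set()
            for g in comp:
                if g.genome_id in seen:
                    raise AssertionError(
                        f"two genes of genome {g.genome_id} in one component"
                    )
                seen.add(g.genome_id)
        self.component_census()  # raises on invalid shapes


def solve_ffadj(
    ffadj_model: FFAdjModel,
    time_limit: float | None = None,
    seed: int = 0,
) -> PartialMatching:
    """Solve the model and re-audit F_alpha from the matching itself."""
    import networkx as nx

    x, status, _obj = solve_milp(ffadj_model.model, time_limit=time_limit, seed=seed)
    ne = len(ffadj_model.edges)
    selected = [e for k, e in enumerate(ffadj_model.edges) if x[k] > 0]

    comp_graph = nx.Graph()
    comp_graph.add_edges_from(selected)
    components = [sorted(c) for c in nx.connected_components(comp_graph)]
    components.sort()

    adj_term, sigma_term = score_partial_matching(
        ffadj_model.graph, selected, ffadj_model.gap_limit
    )
    objective = ffadj_model.alpha * adj_term + (1 - ffadj_model.alpha) * sigma_term

    ilp_objective = float(
        np.dot(ffadj_model.model.objective, x)
    )
    matching = PartialMatching(
        selected,
        components,
        objective,
        ilp_objective,
        status,
        model_stats={
            "n_variables": ffadj_model.model.n_variables,
            "n_constraints": ffadj_model.model.n_constraints,
            **{k: v for k, v in ffadj_model.model.meta.items() if k != "kind"},
        },
    )
    matching.validate()
    if status == "optimal" and not math.isclose(
        objective, ilp_objective, rel_tol=1e-6, abs_tol=1e-6
    ):
        raise AssertionError(
            f"audited F_alpha {objective} != ILP objective {ilp_objective}"
        )
    return matching


def solve_ffadj_graph(
    graph: SimilarityGraph,
    alpha: float = 0.9,
    gap_limit: int = 2,
    fixed_edges: tuple = (),
    time_limit: float | None = None,
    seed: int = 0,
) -> PartialMatching:
    """Convenience: build and solve FFAdj-3G for a similarity graph."""
    model = build_ffadj_ilp(graph, alpha, gap_limit, fixed_edges)
    return solve_ffadj(model, time_limit=time_limit, seed=seed)
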