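"""Brute-force exact solvers for tiny instances.

These are the ground truth for equivalence tests of the ILP solvers.  The
scoring here deliberately re-derives everything from raw similarities and
extant gene orders (no solver code paths are reused): adjacency weights are
recomputed from sigma, conserved adjacencies of a matching are recomputed by
scanning gene orders.  Hard size guards keep the exhaustive searches honest.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable

from .genomes_io import Extremity, Gene, Genome, HEAD, TAIL
from .median_model import FFMedianInstance, MedianCandidate
from .simgraph import SimilarityGraph


class OracleSizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FF-Median oracle
# ---------------------------------------------------------------------------

def _independent_weight(adj, graph: SimilarityGraph, genomes) -> float:
    """Recompute an adjacency weight from raw sigma and extant adjacencies."""

    def tri_score(m: MedianCandidate) -> float:
        if m.is_telomeric:
            return 1.0
        g, h, i = m.genes
        return (graph.sigma(g, h) * graph.sigma(g, i) * graph.sigma(h, i)) ** (1 / 3)

    (m1, a), (m2, b) = adj.ends
    s = math.sqrt(tri_score(m1) * tri_score(m2))
    total = 0.0
    for X in genomes:
        e1 = Extremity(m1.projection(X.id), a)
        e2 = Extremity(m2.projection(X.id), b)
        if frozenset({e1, e2}) in X.adjacencies:
            total += s
    return total


def brute_force_median(
    instance: FFMedianInstance,
    max_candidates: int = 14,
    max_adjacencies: int = 26,
) -> tuple[float, list]:
    """Exhaustive optimum of FF-Median over conserved candidate adjacencies.

    Enumerates adjacency subsets (with branch-and-bound pruning) subject to
    conflict-freeness of the induced candidate set and extremity degree <= 1.
    Returns (optimal objective, one optimal adjacency subset).
    """
    if len(instance.candidates) > max_candidates:
        raise OracleSizeError(
            f"{len(instance.candidates)} candidates exceed guard {max_candidates}"
        )
    if len(instance.adjacencies) > max_adjacencies:
        raise OracleSizeError(
            f"{len(instance.adjacencies)} adjacencies exceed guard {max_adjacencies}"
        )

    adjs = instance.adjacencies
    weights = [
        _independent_weight(adj, instance.graph, instance.genomes) for adj in adjs
    ]
    suffix = [0.0] * (len(adjs) + 1)
    for k in range(len(adjs) - 1, -1, -1):
        suffix[k] = suffix[k + 1] + weights[k]

    best = {"obj": 0.0, "sel": []}

    def compatible(adj, owner: dict[Gene, MedianCandidate], used: set) -> bool:
        for m, side in adj.ends:
            if (m, side) in used:
                return False
            for gene in m.genes:
                if owner.get(gene, m) != m:
                    return False
        return True

    def rec(k: int, owner: dict, used: set, sel: list, total: float) -> None:
        if total > best["obj"]:
            best["obj"] = total
            best["sel"] = list(sel)
        if k == len(adjs) or total + suffix[k] <= best["obj"]:
            return
        adj = adjs[k]
        if compatible(adj, owner, used):
            added_genes = []
            for m, side in adj.ends:
                used.add((m, side))
                for gene in m.genes:
                    if gene not in owner:
                        owner[gene] = m
                        added_genes.append(gene)
            sel.append(adj)
            rec(k + 1, owner, used, sel, total + weights[k])
            sel.pop()
            for gene in added_genes:
                del owner[gene]
            for m, side in adj.ends:
                used.discard((m, side))
        rec(k + 1, owner, used, sel, total)

    rec(0, {}, set(), [], 0.0)
    return best["obj"], best["sel"]


# ---------------------------------------------------------------------------
# FF-Adjacencies oracle
# ---------------------------------------------------------------------------

def _induced_adjacencies(
    X: Genome, matched: set[Gene], gap_limit: int
) -> set[frozenset]:
    """Adjacencies of the subgenome of ``X`` induced by ``matched`` genes,
    restricted to gaps of at most ``gap_limit`` skipped genes."""

    def left(gene, sign):
        return Extremity(gene, TAIL if sign > 0 else HEAD)

    def right(gene, sign):
        return Extremity(gene, HEAD if sign > 0 else TAIL)

    out: set[frozenset] = set()
    for chrom in X.chromosomes:
        order = [(g, s) for g, s in chrom.order if g in matched]
        positions = {g: p for p, (g, _s) in enumerate(chrom.order)}
        n_all = len(chrom.order)
        if chrom.topology == "linear":
            for (g1, s1), (g2, s2) in zip(order, order[1:]):
                gap = positions[g2] - positions[g1] - 1
                if gap <= gap_limit:
                    out.add(frozenset({right(g1, s1), left(g2, s2)}))
        else:
            if len(order) >= 2:
                for k in range(len(order)):
                    g1, s1 = order[k]
                    g2, s2 = order[(k + 1) % len(order)]
                    gap = (positions[g2] - positions[g1] - 1) % n_all
                    if gap <= gap_limit:
                        out.add(frozenset({right(g1, s1), left(g2, s2)}))
    return out


def _matching_is_valid(edges: list[tuple[Gene, Gene]]) -> bool:
    """Definition check: every connected component has at most one gene per
    genome (partial 3-matching)."""
    parent: dict[Gene, Gene] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for x, y in edges:
        for v in (x, y):
            parent.setdefault(v, v)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry
    groups: dict[Gene, set[str]] = {}
    for v in parent:
        root = find(v)
        seen = groups.setdefault(root, set())
        if v.genome_id in seen:
            return False
        seen.add(v.genome_id)
    return True


def score_partial_matching(
    graph: SimilarityGraph,
    edges: Iterable[tuple[Gene, Gene]],
    gap_limit: int,
) -> tuple[float, float]:
    """(conserved-adjacency term, similarity term) of a partial 3-matching,
    recomputed from scratch by scanning the extant gene orders."""
    edges = list(edges)
    sigma_term = sum(graph.sigma(x, y) for x, y in edges)
    matched_by_genome: dict[str, set[Gene]] = {g.id: set() for g in graph.genomes}
    partner: dict[tuple[Gene, str], Gene] = {}
    for x, y in edges:
        matched_by_genome[x.genome_id].add(x)
        matched_by_genome[y.genome_id].add(y)
        partner[(x, y.genome_id)] = y
        partner[(y, x.genome_id)] = x

    genomes = graph.genomes
    induced = {
        X.id: _induced_adjacencies(X, matched_by_genome[X.id], gap_limit)
        for X in genomes
    }
    adj_term = 0.0
    for X, Y in itertools.combinations(genomes, 2):
        for adj in induced[X.id]:
            e1, e2 = tuple(adj)
            y1 = partner.get((e1.gene, Y.id))
            y2 = partner.get((e2.gene, Y.id))
            if y1 is None or y2 is None or y1 == y2:
                continue
            mirrored = frozenset(
                {Extremity(y1, e1.side), Extremity(y2, e2.side)}
            )
            if mirrored in induced[Y.id]:
                adj_term += math.sqrt(
                    graph.sigma(e1.gene, y1) * graph.sigma(e2.gene, y2)
                )
    return adj_term, sigma_term


def brute_force_ffadj(
    graph: SimilarityGraph,
    alpha: float | Iterable[float],
    gap_limit: int,
    max_edges: int = 26,
) -> dict[float, float] | float:
    """Exhaustive optimum of FF-Adjacencies over all valid matchings.

    Recursively enumerates exactly the edge subsets satisfying the partial
    3-matching definition (components of at most three genes, one per
    genome), scoring each from scratch.  ``alpha`` may be a single value or
    an iterable; the per-subset adjacency and similarity terms are computed
    once and combined per alpha.  Returns a float for a single alpha, else a
    dict alpha -> optimum.
    """
    single = isinstance(alpha, (int, float))
    alphas = [float(alpha)] if single else [float(a) for a in alpha]
    edges = [(x, y) for x, y, _s in graph.edges()]
    if len(edges) > max_edges:
        raise OracleSizeError(f"{len(edges)} edges exceed guard {max_edges}")

    best = {a: 0.0 for a in alphas}
    subset: list[tuple[Gene, Gene]] = []

    def score_current() -> None:
        adj_term, sigma_term = score_partial_matching(graph, subset, gap_limit)
        for a in alphas:
            val = a * adj_term + (1 - a) * sigma_term
            if val > best[a]:
                best[a] = val

    def rec(k: int, comp: dict[Gene, int], genomes_of: dict[int, frozenset]) -> None:
        score_current()
        for j in range(k, len(edges)):
            x, y = edges[j]
            cx, cy = comp.get(x), comp.get(y)
            if cx is not None and cx == cy:
                new_comp, new_g = comp, genomes_of  # closing a triangle
            else:
                gx = genomes_of.get(cx, frozenset({x.genome_id}))
                gy = genomes_of.get(cy, frozenset({y.genome_id}))
                if gx & gy or len(gx | gy) > 3:
                    continue
                new_comp = dict(comp)
                for node, c in comp.items():
                    if c is not None and c in (cx, cy):
                        new_comp[node] = j
                new_comp[x] = j
                new_comp[y] = j
                new_g = dict(genomes_of)
                new_g[j] = gx | gy
            subset.append((x, y))
            rec(j + 1, new_comp, new_g)
            subset.pop()

    rec(0, {}, {})
    return best[alphas[0]] if single else best
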