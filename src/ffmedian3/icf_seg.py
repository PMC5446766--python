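"""Local-optimality preprocessing for FF-Median (ICF-SEG).

An *IC-free run* is a sequence of pairwise non-conflicting candidate median
genes whose projections are consecutive in every extant genome, in the same
order or its full reversal.  For such a run S, a matching graph Gamma'(S) is
built: vertices are the extremities of the candidates of S, regular edges
are the candidate adjacencies restricted to S (weighted as in the median
instance), and each candidate m additionally gets a *conflict edge*
{m^h, m^t} weighted by w'(m), the maximum total potential of a conflict-free
subset of the candidates externally conflicting with m.  The potential
Delta(m) of a candidate is an upper bound on its achievable contribution to
any median: the maximum incident adjacency weight at each extremity, summed.

If a maximum-weight matching in Gamma'(S) avoids all conflict edges, the
matched adjacencies belong to at least one optimal median: they are fixed,
and the instance is reduced by removing externally conflicting candidates,
the run-internal adjacencies, and adjacencies competing for saturated
extremities.  Runs failing the test are retried on their maximal proper
prefix and suffix.  Overestimating w' (the fallback used when exhaustive
subset search is too large) can only reject a run, never fix it wrongly, so
safety is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .genomes_io import CIRCULAR, Extremity, HEAD, TAIL
from .median_model import (
    CandidateAdjacency,
    FFMedianInstance,
    MedianCandidate,
    _ext_key,
)

#: scale for integer matching weights (avoids float ties in the MWM)
_MWM_SCALE = 10**9


@dataclass
class Segment:
    """An IC-free run: ordered candidates with (H, I) step directions
    relative to the forward direction in G (None for length-1 chains)."""

    members: tuple[MedianCandidate, ...]
    directions: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.members)

    @property
    def key(self):
        return tuple(m.key for m in self.members)


def _positions(instance: FFMedianInstance, m: MedianCandidate):
    """Per-genome (chromosome, position) of the candidate's projections."""
    return tuple(
        X.position(m.projection(X.id)) for X in instance.genomes
    )


def find_ic_free_runs(instance: FFMedianInstance) -> list[Segment]:
    """Maximal IC-free runs, longest first then lexicographic.

    Successor links are followed only where they are unambiguous (a unique
    successor whose predecessor is unique as well); per-genome step
    directions must stay constant along a run.
    """
    gene_cands = [m for m in instance.candidates if not m.is_telomeric]
    pos = {m: _positions(instance, m) for m in gene_cands}
    by_gpos: dict[tuple[int, int], list[MedianCandidate]] = {}
    for m in gene_cands:
        by_gpos.setdefault(pos[m][0], []).append(m)

    genomes = instance.genomes
    chrom_len = {
        X.id: [len(c.order) for c in X.chromosomes] for X in genomes
    }

    def unit_step(genome_idx: int, c1: int, p1: int, c2: int, p2: int) -> int | None:
        """+-1 if the two positions are consecutive on one chromosome
        (with circular wrap-around), else None."""
        X = genomes[genome_idx]
        if c1 != c2:
            return None
        d = p2 - p1
        if X.chromosomes[c1].topology == CIRCULAR:
            n = chrom_len[X.id][c1]
            d = (d + n) % n
            if d == 1:
                return 1
            if d == n - 1:
                return -1
            return None
        return d if abs(d) == 1 else None

    def common_pattern(m: MedianCandidate, m2: MedianCandidate) -> bool:
        """True iff the same extremity pair of (m, m2) is an adjacency in
        every genome: order and orientation conserved up to full reversal."""
        patterns = None
        for X in genomes:
            x1, x2 = m.projection(X.id), m2.projection(X.id)
            here = {
                (a, b)
                for a in (HEAD, TAIL)
                for b in (HEAD, TAIL)
                if frozenset({Extremity(x1, a), Extremity(x2, b)})
                in X.adjacencies
            }
            patterns = here if patterns is None else patterns & here
            if not patterns:
                return False
        return True

    def links_from(m: MedianCandidate):
        """Candidates one step to the right in G, consecutive in H and I,
        with a genome-independent exposed extremity pair."""
        (cg, pg), (ch, ph), (ci, pi) = pos[m]
        out = []
        X0 = genomes[0]
        succ_positions = [(cg, pg + 1)]
        if X0.chromosomes[cg].topology == CIRCULAR:
            succ_positions = [(cg, (pg + 1) % chrom_len[X0.id][cg])]
        for gpos in succ_positions:
            for m2 in by_gpos.get(gpos, ()):
                if m2 == m:
                    continue
                (_, _), (ch2, ph2), (ci2, pi2) = pos[m2]
                dh = unit_step(1, ch, ph, ch2, ph2)
                di = unit_step(2, ci, pi, ci2, pi2)
                if dh is None or di is None:
                    continue
                if not common_pattern(m, m2):
                    continue
                out.append((m2, dh, di))
        return out

    successor: dict[MedianCandidate, tuple[MedianCandidate, int, int]] = {}
    indegree: dict[MedianCandidate, int] = {}
    for m in gene_cands:
        lks = links_from(m)
        if len(lks) == 1:
            successor[m] = lks[0]
            indegree[lks[0][0]] = indegree.get(lks[0][0], 0) + 1
    # keep only links whose target has a unique incoming link
    successor = {
        m: lk for m, lk in successor.items() if indegree.get(lk[0], 0) == 1
    }

    has_pred = {lk[0] for lk in successor.values()}
    runs: list[Segment] = []
    for start in sorted(gene_cands):
        if start in has_pred:
            continue
        chain = [start]
        dirs: tuple[int, int] | None = None
        m = start
        while m in successor:
            m2, dh, di = successor[m]
            if dirs is None:
                dirs = (dh, di)
            elif (dh, di) != dirs:
                # direction change: the remainder forms its own run
                runs.append(Segment(tuple(chain), dirs))
                chain = []
                dirs = None
            chain.append(m2)
            m = m2
        runs.append(Segment(tuple(chain), dirs))

    runs = [r for r in runs if len(r) >= 2]
    runs.sort(key=lambda r: (-len(r), r.key))
    return runs


def potential(m: MedianCandidate, instance: FFMedianInstance) -> float:
    """Delta(m): per extremity, the best incident adjacency weight, summed."""
    total = 0.0
    for side in m.sides:
        adjs = instance.adjacencies_at((m, side))
        if adjs:
            total += max(adj.weight for adj in adjs)
    return total


def max_conflict_free_potential(
    conflicts: list[MedianCandidate],
    instance: FFMedianInstance,
    exact_limit: int = 12,
) -> float:
    """w'(m): max total potential of a conflict-free subset of ``conflicts``.

    Exhaustive search up to ``exact_limit`` members; beyond that the sum of
    all potentials is used as a safe overestimate.
    """
    deltas = [potential(c, instance) for c in conflicts]
    if len(conflicts) > exact_limit:
        return sum(deltas)
    from .median_model import conflicting

    best = 0.0

    def rec(k: int, chosen: list[MedianCandidate], total: float) -> None:
        nonlocal best
        best = max(best, total)
        if k == len(conflicts):
            return
        c = conflicts[k]
        if all(not conflicting(c, o) for o in chosen):
            chosen.append(c)
            rec(k + 1, chosen, total + deltas[k])
            chosen.pop()
        rec(k + 1, chosen, total)

    rec(0, [], 0.0)
    return best


def build_gamma_prime(
    segment: Segment,
    instance: FFMedianInstance,
    exact_limit: int = 12,
) -> nx.Graph:
    """The matching graph Gamma'(S): regular adjacency edges plus conflict
    edges {m^h, m^t} weighted w'(m)."""
    members = set(segment.members)
    graph = nx.Graph()
    for m in segment.members:
        for side in m.sides:
            graph.add_node((m, side))
    seen = set()
    for m in segment.members:
        for side in m.sides:
            for adj in instance.adjacencies_at((m, side)):
                (m1, a), (m2, b) = adj.ends
                if m1 in members and m2 in members and adj.key not in seen:
                    seen.add(adj.key)
                    if m1 == m2 and len(segment) > 1:
                        # contiguity makes w({m^h, m^t}) = 0 inside runs
                        raise AssertionError(
                            f"internal self-adjacency in run: {adj!r}"
                        )
                    graph.add_edge((m1, a), (m2, b), weight=adj.weight, conflict=False)
    for m in segment.members:
        conflicts = sorted(instance.conflicts_of(m) - members)
        w_prime = max_conflict_free_potential(conflicts, instance, exact_limit)
        # a zero-weight conflict edge can never beat a conflict-free matching
        # of the same weight, so omitting it loses nothing and avoids
        # spurious rejections on ties against zero
        if w_prime > 0:
            graph.add_edge((m, HEAD), (m, TAIL), weight=w_prime, conflict=True)
    return graph


def _max_weight_matching(graph: nx.Graph):
    """Exact MWM with integer-scaled weights for determinism."""
    scaled = nx.Graph()
    scaled.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        scaled.add_edge(u, v, weight=round(data["weight"] * _MWM_SCALE))
    return nx.max_weight_matching(scaled, maxcardinality=False)


@dataclass
class ICFReport:
    n_runs_found: int = 0
    n_runs_fixed: int = 0
    n_candidates_fixed: int = 0
    n_adjacencies_fixed: int = 0
    n_candidates_removed: int = 0


def icf_seg(
    instance: FFMedianInstance,
    exact_limit: int = 12,
) -> tuple[list[CandidateAdjacency], FFMedianInstance, ICFReport]:
    """Fix locally optimal runs and return (fixed adjacencies, reduced
    instance, report).

    Runs are processed longest first; a run whose maximum-weight matching in
    Gamma' picks a conflict edge is retried on its maximal proper prefix and
    suffix.  Runs touching already fixed or removed candidates are skipped.
    """
    runs = find_ic_free_runs(instance)
    report = ICFReport(n_runs_found=len(runs))
    worklist = list(runs)
    queued = {r.key for r in worklist}
    fixed_adjacencies: list[CandidateAdjacency] = []
    fixed_candidates: set[MedianCandidate] = set()
    removed: set[MedianCandidate] = set()
    masked: list[CandidateAdjacency] = []
    current = instance

    while worklist:
        worklist.sort(key=lambda r: (-len(r), r.key))
        segment = worklist.pop(0)
        if any(m in fixed_candidates or m in removed for m in segment.members):
            continue
        gamma = build_gamma_prime(segment, current, exact_limit)
        matching = _max_weight_matching(gamma)
        if any(
            gamma.edges[u, v]["conflict"] for u, v in matching
        ) or not matching:
            if len(segment) > 2:
                for sub in (segment.members[:-1], segment.members[1:]):
                    key = tuple(m.key for m in sub)
                    if key not in queued:
                        queued.add(key)
                        worklist.append(Segment(tuple(sub), segment.directions))
            continue

        # conflict-free MWM: fix the matched adjacencies
        adj_by_ends = {adj.key: adj for adj in current.adjacencies}
        matched_adjs = []
        matched_exts = set()
        for u, v in matching:
            key = frozenset({_ext_key(u), _ext_key(v)})
            matched_adjs.append(adj_by_ends[key])
            matched_exts.update((u, v))
        fixed_adjacencies.extend(matched_adjs)
        fixed_candidates.update(segment.members)
        report.n_runs_fixed += 1
        report.n_candidates_fixed += len(segment.members)
        report.n_adjacencies_fixed += len(matched_adjs)

        member_set = set(segment.members)
        external = set()
        for m in segment.members:
            external |= current.conflicts_of(m) - member_set
        removed |= external
        report.n_candidates_removed += len(external)

        drop_adjs = set()
        for adj in current.adjacencies:
            m1, m2 = adj.candidates
            internal = m1 in member_set and m2 in member_set
            competes = any(end in matched_exts for end in adj.ends)
            if internal or competes:
                drop_adjs.add(adj.key)
        masked.extend(a for a in current.adjacencies if a.key in drop_adjs)
        current = current.reduced(
            drop_candidates=external,
            drop_adjacencies=[a for a in current.adjacencies if a.key in drop_adjs],
        )

    return fixed_adjacencies, current, report
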