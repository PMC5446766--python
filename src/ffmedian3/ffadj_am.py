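"""FFAdj-AM: FF-Median as a fixed partial solution for FFAdj-3G.

The heuristic first solves FF-Median (with ICF-SEG preprocessing), converts
the median into a partial 3-matching (each median gene (g, h, i) contributes
the triangle {g,h}, {g,i}, {h,i}; conflict-freeness of the median guarantees
Definition-1 feasibility), and then runs FFAdj-3G over the full similarity
graph with those edges forced.  Searching the full graph rather than the
median-free residue lets conserved adjacencies span median-derived and newly
added components.  The result can only improve on the median-induced score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ffadj import PartialMatching, build_ffadj_ilp, solve_ffadj
from .genomes_io import Gene
from .icf_seg import icf_seg
from .median_model import build_instance
from .median_solver import Median, build_ffmedian_ilp, solve
from .oracle import _matching_is_valid, score_partial_matching
from .simgraph import SimilarityGraph


def median_to_matching(median: Median) -> list[tuple[Gene, Gene]]:
    """The partial 3-matching implied by a median: one triangle per median
    gene (telomere triples carry no similarity edges and are skipped)."""
    median.validate()  # conflict-freeness guard
    edges = []
    for m in median.candidates:
        if m.is_telomeric:
            continue
        g, h, i = m.genes
        edges.extend([(g, h), (g, i), (h, i)])
    if not _matching_is_valid(edges):
        raise AssertionError("median does not induce a valid partial 3-matching")
    return edges


def compute_median(
    graph: SimilarityGraph,
    use_icf_seg: bool = True,
    keep_unsupported: bool = False,
    time_limit: float | None = None,
    seed: int = 0,
) -> tuple[Median, dict]:
    """Full FF-Median pipeline: instance, optional ICF-SEG, ILP, recombine."""
    instance = build_instance(graph, keep_unsupported=keep_unsupported)
    info: dict = {"instance": instance.stats}
    fixed = []
    reduced = instance
    if use_icf_seg:
        fixed, reduced, report = icf_seg(instance)
        info["icf_seg"] = vars(report)
    model = build_ffmedian_ilp(reduced)
    partial = solve(model, reduced, time_limit=time_limit, seed=seed)
    all_adjs = fixed + partial.adjacencies
    used = {m for adj in all_adjs for m in adj.candidates}
    median = Median(
        sorted(used),
        all_adjs,
        sum(a.weight for a in all_adjs),
        partial.status,
        model_stats=partial.model_stats,
    )
    median.validate()
    return median, info


@dataclass
class FFAdjAMResult:
    matching: PartialMatching
    median: Median
    #: per component: "median" if it contains a median-derived edge else "ffadj"
    provenance: list[str] = field(default_factory=list)
    info: dict = field(default_factory=dict)


def ffadj_am(
    graph: SimilarityGraph,
    alpha: float = 0.9,
    gap_limit: int = 2,
    time_limits: tuple[float | None, float | None] = (None, None),
    seed: int = 0,
    use_icf_seg: bool = True,
) -> FFAdjAMResult:
    median, info = compute_median(
        graph, use_icf_seg=use_icf_seg, time_limit=time_limits[0], seed=seed
    )
    fixed_edges = median_to_matching(median)

    model = build_ffadj_ilp(
        graph, alpha, gap_limit=gap_limit, fixed_edges=tuple(fixed_edges)
    )
    matching = solve_ffadj(model, time_limit=time_limits[1], seed=seed)

    # dominance audit: forcing can only improve on the median-induced score
    adj_t, sig_t = score_partial_matching(graph, fixed_edges, gap_limit)
    median_score = alpha * adj_t + (1 - alpha) * sig_t
    if matching.status == "optimal" and matching.objective < median_score - 1e-9:
        raise AssertionError(
            f"FFAdj-AM score {matching.objective} below median-induced "
            f"score {median_score}"
        )
    info["median_induced_score"] = median_score

    fixed_set = {frozenset(e) for e in fixed_edges}
    provenance = []
    for comp in matching.components:
        comp_set = set(comp)
        has_median_edge = any(
            frozenset(e) in fixed_set
            for e in matching.edges
            if e[0] in comp_set and e[1] in comp_set
        )
        provenance.append("median" if has_median_edge else "ffadj")
    return FFAdjAMResult(matching, median, provenance, info)
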