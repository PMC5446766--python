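"""FF-Median instance construction: candidate median genes and adjacencies.

A candidate median gene is a triple (g, h, i), one gene per genome, whose
three pairwise similarities are all positive (a 3-clique, i.e. triangle, of
the tripartite similarity graph); its score is the geometric mean of the
three pairwise similarities.  Two candidates conflict when they share an
extant gene; a median must be conflict-free.

Candidate median adjacencies pair extremities of non-conflicting candidates
and are weighted by the sum, over extant genomes in which the projected
adjacency is present, of the adjacency score

    s(m1^a, pi_X(m1)^a, m2^b, pi_X(m2)^b) = sqrt(score(m1) * score(m2)),

the sixth root of the product of the six pairwise similarities of the two
candidates.  Only *conserved* candidate adjacencies (present in at least one
extant genome, hence weight > 0) can contribute to the objective and are
enumerated.

Telomeres are modelled explicitly: telomere triples (one telomere per
genome) are admissible candidates with score sigma(o, o) := 1, instantiated
only when they support at least one conserved candidate adjacency.

By default, genes that are part of no 3-clique are discarded from the extant
gene orders before adjacencies are extracted (they cannot be part of any
median, and removing them can restore adjacencies disrupted by insertions);
``keep_unsupported=True`` disables this.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genomes_io import (
    HEAD,
    TAIL,
    TELOMERIC,
    Extremity,
    Gene,
    Genome,
)
from .simgraph import SimilarityGraph


@dataclass(frozen=True, order=True)
class MedianCandidate:
    """A candidate median gene: one (tel)gene per genome, with its score."""

    g: Gene
    h: Gene
    i: Gene
    score: float = field(compare=False)

    @property
    def genes(self) -> tuple[Gene, Gene, Gene]:
        return (self.g, self.h, self.i)

    @property
    def is_telomeric(self) -> bool:
        return self.g.is_telomere

    @property
    def sides(self) -> tuple[str, ...]:
        return (TELOMERIC,) if self.is_telomeric else (HEAD, TAIL)

    def projection(self, genome_id: str) -> Gene:
        for gene in self.genes:
            if gene.genome_id == genome_id:
                return gene
        raise KeyError(genome_id)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.g.id, self.h.id, self.i.id)

    def __repr__(self) -> str:
        return f"({self.g.id},{self.h.id},{self.i.id})"


#: An extremity of a candidate median gene: (candidate, side).
CandExtremity = tuple[MedianCandidate, str]


def _ext_key(ext: CandExtremity):
    cand, side = ext
    return (*cand.key, side)


@dataclass(frozen=True)
class CandidateAdjacency:
    """A conserved candidate median adjacency {m1^a, m2^b} with weight w."""

    end1: CandExtremity
    end2: CandExtremity
    weight: float
    support: frozenset[str]  # genome ids in which the projection is an adjacency

    @property
    def ends(self) -> tuple[CandExtremity, CandExtremity]:
        return (self.end1, self.end2)

    @property
    def candidates(self) -> tuple[MedianCandidate, MedianCandidate]:
        return (self.end1[0], self.end2[0])

    @property
    def key(self):
        return frozenset({_ext_key(self.end1), _ext_key(self.end2)})

    def __repr__(self) -> str:
        (m1, a), (m2, b) = self.end1, self.end2
        return f"{{{m1!r}^{a}, {m2!r}^{b}}} w={self.weight:.4g} [{','.join(sorted(self.support))}]"


def median_gene_score(sigma_gh: float, sigma_gi: float, sigma_hi: float) -> float:
    """Geometric mean of the three pairwise similarities of a triple."""
    return (sigma_gh * sigma_gi * sigma_hi) ** (1.0 / 3.0)


def adjacency_score(
    e1a: Extremity, e1b: Extremity, e2a: Extremity, e2b: Extremity, sigma
) -> float:
    """sqrt(sigma(gene1a, gene1b) * sigma(gene2a, gene2b)).

    ``sigma`` is a callable on gene pairs; telomere-telomere similarity is
    taken as 1 and telomere-gene similarity as 0, so the formula specializes
    cleanly to capped adjacencies.
    """

    def _sig(x: Gene, y: Gene) -> float:
        if x.is_telomere and y.is_telomere:
            return 1.0
        if x.is_telomere or y.is_telomere:
            return 0.0
        return sigma(x, y)

    return math.sqrt(_sig(e1a.gene, e1b.gene) * _sig(e2a.gene, e2b.gene))


def conflicting(m1: MedianCandidate, m2: MedianCandidate) -> bool:
    """True iff distinct candidates share an extant gene (or telomere)."""
    return m1 != m2 and any(a == b for a, b in zip(m1.genes, m2.genes))


def enumerate_candidates(graph: SimilarityGraph) -> list[MedianCandidate]:
    """All tripartite triangles of the similarity graph, sorted by gene ids."""
    G, H, I = graph.genomes
    out = []
    for g in sorted(graph._neighbours):
        if g.genome_id != G.id:
            continue
        for h in graph.neighbours(g, H.id):
            s_gh = graph.sigma(g, h)
            for i in graph.neighbours(g, I.id):
                s_hi = graph.sigma(h, i)
                if s_hi > 0:
                    score = median_gene_score(s_gh, graph.sigma(g, i), s_hi)
                    out.append(MedianCandidate(g, h, i, score))
    out.sort()
    return out


class FFMedianInstance:
    """A built FF-Median instance: candidates, conserved adjacencies, conflicts."""

    def __init__(
        self,
        graph: SimilarityGraph,
        genomes: tuple[Genome, Genome, Genome],
        candidates: Sequence[MedianCandidate],
        adjacencies: Sequence[CandidateAdjacency],
    ):
        self.graph = graph
        self.genomes = tuple(genomes)  # possibly content-filtered copies
        self.candidates = sorted(candidates)
        self.adjacencies = sorted(adjacencies, key=lambda a: sorted(a.key))
        # conflict index: extant gene -> candidates containing it
        self.by_gene: dict[Gene, list[MedianCandidate]] = {}
        for m in self.candidates:
            for gene in m.genes:
                self.by_gene.setdefault(gene, []).append(m)
        # adjacency index by candidate extremity
        self.by_extremity: dict[CandExtremity, list[CandidateAdjacency]] = {}
        for adj in self.adjacencies:
            for end in adj.ends:
                self.by_extremity.setdefault(end, []).append(adj)

    def conflicts_of(self, m: MedianCandidate) -> set[MedianCandidate]:
        out: set[MedianCandidate] = set()
        for gene in m.genes:
            out.update(self.by_gene.get(gene, ()))
        out.discard(m)
        return out

    def adjacencies_at(self, ext: CandExtremity) -> list[CandidateAdjacency]:
        return self.by_extremity.get(ext, [])

    def reduced(
        self,
        drop_candidates: Iterable[MedianCandidate] = (),
        drop_adjacencies: Iterable[CandidateAdjacency] = (),
    ) -> "FFMedianInstance":
        """A copy without the given candidates (and their adjacencies) and
        without the explicitly dropped adjacencies."""
        dropped_c = set(drop_candidates)
        dropped_a = {a.key for a in drop_adjacencies}
        cands = [m for m in self.candidates if m not in dropped_c]
        adjs = [
            a
            for a in self.adjacencies
            if a.key not in dropped_a and not (set(a.candidates) & dropped_c)
        ]
        return FFMedianInstance(self.graph, self.genomes, cands, adjs)

    @property
    def stats(self) -> dict:
        return {
            "n_candidates": len(self.candidates),
            "n_telomere_candidates": sum(m.is_telomeric for m in self.candidates),
            "n_adjacencies": len(self.adjacencies),
        }

    def __repr__(self) -> str:
        s = self.stats
        return (
            f"FFMedianInstance({s['n_candidates']} candidates, "
            f"{s['n_adjacencies']} adjacencies)"
        )


def enumerate_conserved_adjacencies(
    candidates: Sequence[MedianCandidate],
    genomes: tuple[Genome, Genome, Genome],
    graph: SimilarityGraph,
) -> list[CandidateAdjacency]:
    """All conserved candidate adjacencies with their Eq-style weights.

    Iterates extant adjacencies and lifts them to pairs of candidate
    extremities; the weight is |support| * sqrt(score(m1) * score(m2)).
    """
    # map extant extremity -> candidate extremities projecting onto it
    lift: dict[Extremity, list[CandExtremity]] = {}
    for m in candidates:
        for gene in m.genes:
            if m.is_telomeric:
                lift.setdefault(Extremity(gene, TELOMERIC), []).append((m, TELOMERIC))
            else:
                for side in (HEAD, TAIL):
                    lift.setdefault(Extremity(gene, side), []).append((m, side))

    support: dict[frozenset, set[str]] = {}
    ends_of: dict[frozenset, tuple[CandExtremity, CandExtremity]] = {}
    for X in genomes:
        for adj in X.adjacencies:
            e1, e2 = tuple(adj)
            for end1 in lift.get(e1, ()):
                for end2 in lift.get(e2, ()):
                    m1, m2 = end1[0], end2[0]
                    if m1 == m2 or conflicting(m1, m2):
                        continue
                    key = frozenset({_ext_key(end1), _ext_key(end2)})
                    support.setdefault(key, set()).add(X.id)
                    ends_of[key] = tuple(sorted((end1, end2), key=_ext_key))

    out = []
    for key, genome_ids in support.items():
        end1, end2 = ends_of[key]
        w = len(genome_ids) * math.sqrt(end1[0].score * end2[0].score)
        if w > 0:
            out.append(
                CandidateAdjacency(end1, end2, w, frozenset(genome_ids))
            )
    out.sort(key=lambda a: sorted(a.key))
    return out


def _telomere_triples(genomes: tuple[Genome, Genome, Genome]) -> list[MedianCandidate]:
    """All combinations of one telomere per genome, score sigma(o,o) = 1."""
    tg, th, ti = (genome.telomeres for genome in genomes)
    return [
        MedianCandidate(a, b, c, 1.0) for a, b, c in itertools.product(tg, th, ti)
    ]


def build_instance(
    graph: SimilarityGraph,
    keep_unsupported: bool = False,
    include_telomeres: bool = True,
) -> FFMedianInstance:
    """Build the FF-Median instance for a similarity graph.

    Candidate enumeration, optional discarding of genes outside every
    3-clique, telomere-triple instantiation, and conserved-adjacency
    enumeration.  Telomere triples that end up with no incident conserved
    adjacency are pruned to keep the instance small.
    """
    candidates = enumerate_candidates(graph)
    genomes = graph.genomes
    if not keep_unsupported:
        supported = {gene for m in candidates for gene in m.genes}
        genomes = tuple(g.restricted_to(supported) for g in genomes)

    all_candidates = list(candidates)
    if include_telomeres:
        all_candidates.extend(_telomere_triples(genomes))

    adjacencies = enumerate_conserved_adjacencies(all_candidates, genomes, graph)

    used = {m for adj in adjacencies for m in adj.candidates}
    pruned = [m for m in all_candidates if not m.is_telomeric or m in used]
    return FFMedianInstance(graph, genomes, pruned, adjacencies)


def write_instance(instance: FFMedianInstance, prefix: str | Path) -> None:
    """Debug dump: TSVs of candidates with scores and adjacencies with
    weights and support masks."""
    prefix = Path(prefix)
    with prefix.with_suffix(".candidates.tsv").open("w") as fh:
        for m in instance.candidates:
            fh.write(f"{m.g.id}\t{m.h.id}\t{m.i.id}\t{m.score:.10g}\n")
    with prefix.with_suffix(".adjacencies.tsv").open("w") as fh:
        for adj in instance.adjacencies:
            (m1, a), (m2, b) = adj.ends
            mask = ",".join(sorted(adj.support))
            fh.write(
                f"{m1!r}^{a}\t{m2!r}^{b}\t{adj.weight:.10g}\t{mask}\n"
            )
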