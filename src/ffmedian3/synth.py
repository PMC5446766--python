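"""Synthetic genome-triple generator with known orthology, plus evaluation
metrics.

The generator evolves an ancestral genome independently along three branches
with inversions, transpositions, segmental duplications and gene losses, and
derives pairwise similarities that decay with divergence.  It emulates only
the statistical structure the family-free methods consume -- a tripartite
similarity graph with triangle signal among true orthologs, decaying scores
and paralogy noise on a rearranged synteny backbone -- not sequence-level
evolution (no codon/AA models; branch distances are abstract units, not PAM).

Event counts on a branch of distance d are Poisson(rate * d); inversions and
transpositions act on random segments with geometric lengths; a duplication
copies one gene to a random position, the new copy losing positional status;
a loss deletes one gene.  The similarity of two genes sharing an ancestral
lineage is

    sigma = exp(-lambda * (d_x + d_y) - dup_penalty * (k_x + k_y)) + noise

where k counts duplications on the gene's path from the ancestor, and the
Gaussian noise scales with the path length (so at distance zero sigma is
exactly 1).  True positional orthologs are pairs of genes that descend from
the same ancestral gene and both kept their syntenic position (no
duplication on their path).

Two observation effects are modelled on top of the decay: homologies whose
similarity falls below a detection threshold are not reported (distant
homologs escape alignment searches), and a small rate of spurious hits
connects unrelated genes.

The default parameters are the generator's study conditions: 200-gene
single-chromosome genomes (a scaled-down bacterial genome), equal branch
lengths, per-unit-distance event rates of 4 inversions, 2 transpositions,
2 duplications and 2 losses, decay lambda = 1.0, noise s.d. 0.05, detection
threshold 0.05 and spurious-hit rate 5e-4 per gene pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomes_io import Gene, Genome, LINEAR
from .simgraph import SimilarityGraph


@dataclass(frozen=True)
class SimulationParams:
    n_genes: int = 200
    n_chromosomes: int = 1
    distances: tuple[float, float, float] = (0.5, 0.5, 0.5)
    inversion_rate: float = 4.0  # expected events per unit distance
    transposition_rate: float = 2.0
    duplication_rate: float = 2.0
    loss_rate: float = 2.0
    segment_mean_length: float = 3.0  # geometric mean length of inv/transp segments
    decay: float = 1.0  # lambda: similarity decay per unit distance
    dup_penalty: float = 0.5  # extra decay per duplication on the path
    noise_sd: float = 0.05
    detection_threshold: float = 0.05  # homologies below this stay unobserved
    spurious_rate: float = 5e-4  # spurious-hit probability per inter-genome pair
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.inversion_rate,
            self.transposition_rate,
            self.duplication_rate,
            self.loss_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be non-negative")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one gene and one chromosome")


@dataclass(frozen=True)
class _Lineage:
    """Evolutionary bookkeeping carried by each simulated gene."""

    ancestor: int  # index of the ancestral gene
    positional: bool  # no duplication displaced this copy
    n_dups: int  # duplications on the path from the ancestor
    sign: int


@dataclass
class TruthTable:
    """Ground truth of a simulated triple."""

    #: extant gene id -> (genome id, ancestral gene index, positional, n_dups)
    lineage: dict[str, tuple[str, int, bool, int]]
    #: true positional-ortholog pairs as frozensets of (genome_id, gene_id)
    true_pairs: frozenset

    def pairs_for(self, genome_x: str, genome_y: str) -> set[frozenset]:
        wanted = {genome_x, genome_y}
        return {
            p for p in self.true_pairs if {gid for gid, _g in p} == wanted
        }


def _evolve_branch(
    rng: np.random.Generator,
    genome: list[_Lineage],
    distance: float,
    params: SimulationParams,
) -> list[_Lineage]:
    genome = list(genome)
    counts = {
        "inversion": rng.poisson(params.inversion_rate * distance),
        "transposition": rng.poisson(params.transposition_rate * distance),
        "duplication": rng.poisson(params.duplication_rate * distance),
        "loss": rng.poisson(params.loss_rate * distance),
    }
    events = [kind for kind, c in counts.items() for _ in range(c)]
    rng.shuffle(events)

    p_seg = 1.0 / params.segment_mean_length
    for kind in events:
        n = len(genome)
        if n == 0:
            break
        if kind == "loss":
            del genome[int(rng.integers(0, n))]
            continue
        if kind == "inversion":
            length = min(int(rng.geometric(p_seg)), n)
            start = int(rng.integers(0, n - length + 1))
            segment = genome[start : start + length]
            genome[start : start + length] = [
                replace(g, sign=-g.sign) for g in reversed(segment)
            ]
        elif kind == "transposition":
            if n < 2:
                continue
            length = min(int(rng.geometric(p_seg)), n - 1)
            start = int(rng.integers(0, n - length + 1))
            segment = genome[start : start + length]
            rest = genome[:start] + genome[start + length :]
            dest = int(rng.integers(0, len(rest) + 1))
            genome = rest[:dest] + segment + rest[dest:]
        else:  # duplication
            src = int(rng.integers(0, n))
            copy = replace(
                genome[src],
                positional=False,
                n_dups=genome[src].n_dups + 1,
            )
            dest = int(rng.integers(0, n + 1))
            genome.insert(dest, copy)
    if not genome:
        raise ValueError("all genes lost: rates too high for this genome size")
    return genome


def simulate_triple(
    params: SimulationParams,
) -> tuple[tuple[Genome, Genome, Genome], SimilarityGraph, TruthTable]:
    """Simulate three genomes from a common ancestor with known orthology."""
    rng = np.random.default_rng(params.seed)
    ancestor = [
        _Lineage(ancestor=k, positional=True, n_dups=0, sign=1)
        for k in range(params.n_genes)
    ]

    genome_ids = ("G", "H", "I")
    evolved = {}
    for gid, d in zip(genome_ids, params.distances):
        evolved[gid] = _evolve_branch(rng, ancestor, d, params)

    # split into chromosomes of roughly equal size, assign extant ids
    genomes = []
    lineage: dict[str, tuple[str, int, bool, int]] = {}
    gene_info: dict[str, list[tuple[Gene, _Lineage]]] = {}
    for gid in genome_ids:
        items = evolved[gid]
        n = len(items)
        k = params.n_chromosomes
        bounds = [round(j * n / k) for j in range(k + 1)]
        chroms = []
        for ci in range(k):
            order = []
            for p in range(bounds[ci], bounds[ci + 1]):
                item = items[p]
                gene_id = f"{gid.lower()}{p:04d}"
                order.append((item.sign, gene_id))
                lineage[gene_id] = (gid, item.ancestor, item.positional, item.n_dups)
            chroms.append((f"chr{ci + 1}", LINEAR, order))
        genome = Genome.from_orders(gid, chroms)
        genomes.append(genome)
        gene_info[gid] = [
            (genome.gene(gene_id), items[p])
            for p, gene_id in enumerate(
                f"{gid.lower()}{p:04d}" for p in range(n)
            )
        ]

    distance_of = dict(zip(genome_ids, params.distances))
    weights: dict[frozenset, float] = {}
    true_pairs: set[frozenset] = set()
    for ai in range(len(genome_ids)):
        for bi in range(ai + 1, len(genome_ids)):
            gx, gy = genome_ids[ai], genome_ids[bi]
            path_d = distance_of[gx] + distance_of[gy]
            by_anc: dict[int, list[tuple[Gene, _Lineage]]] = {}
            for gene, item in gene_info[gy]:
                by_anc.setdefault(item.ancestor, []).append((gene, item))
            for gene_x, item_x in gene_info[gx]:
                for gene_y, item_y in by_anc.get(item_x.ancestor, ()):
                    base = math.exp(
                        -params.decay * path_d
                        - params.dup_penalty * (item_x.n_dups + item_y.n_dups)
                    )
                    noise = rng.normal(0.0, params.noise_sd * min(1.0, path_d))
                    sigma = min(1.0, base + noise)
                    # homologies diverged below the detection threshold are
                    # not observed (alignment search fails to report them)
                    if sigma >= params.detection_threshold or path_d == 0:
                        weights[frozenset({gene_x, gene_y})] = max(sigma, 1e-6)
                    if item_x.positional and item_y.positional:
                        true_pairs.add(
                            frozenset({(gx, gene_x.id), (gy, gene_y.id)})
                        )
            # spurious hits between non-homologous genes
            if params.spurious_rate > 0:
                nx_, ny_ = len(gene_info[gx]), len(gene_info[gy])
                n_spurious = rng.binomial(nx_ * ny_, params.spurious_rate)
                for _ in range(n_spurious):
                    gene_x, item_x = gene_info[gx][int(rng.integers(0, nx_))]
                    gene_y, item_y = gene_info[gy][int(rng.integers(0, ny_))]
                    if item_x.ancestor == item_y.ancestor:
                        continue
                    pair = frozenset({gene_x, gene_y})
                    if pair not in weights:
                        weights[pair] = float(
                            rng.uniform(
                                params.detection_threshold,
                                3 * params.detection_threshold,
                            )
                        )

    graph = SimilarityGraph(tuple(genomes), weights)
    truth = TruthTable(lineage, frozenset(true_pairs))
    return tuple(genomes), graph, truth


def random_similarity_triple(
    seed: int,
    n_genes: int = 5,
    p_edge: float = 0.35,
    circular_prob: float = 0.25,
) -> tuple[tuple[Genome, Genome, Genome], SimilarityGraph]:
    """A small random genome triple with an unstructured similarity graph.

    Unlike :func:`simulate_triple` there is no shared ancestry: gene orders
    are random signed permutations (occasionally on a circular chromosome)
    and every inter-genome gene pair carries an edge with probability
    ``p_edge`` and a uniform weight in (0, 1].  Intended for equivalence
    testing against the brute-force oracles, where adversarially unstructured
    conflict patterns matter more than biological realism.
    """
    rng = np.random.default_rng(seed)
    genomes = []
    for gid in ("G", "H", "I"):
        order = [
            (int(rng.choice([-1, 1])), f"{gid.lower()}{k}") for k in range(n_genes)
        ]
        perm = rng.permutation(n_genes)
        order = [order[int(j)] for j in perm]
        topology = "circular" if rng.random() < circular_prob else LINEAR
        genomes.append(Genome.from_orders(gid, [("c1", topology, order)]))
    weights: dict[frozenset, float] = {}
    for ai in range(3):
        for bi in range(ai + 1, 3):
            for gx in genomes[ai].non_telomeric_genes():
                for gy in genomes[bi].non_telomeric_genes():
                    if rng.random() < p_edge:
                        weights[frozenset({gx, gy})] = float(
                            rng.uniform(0.05, 1.0)
                        )
    return tuple(genomes), SimilarityGraph(tuple(genomes), weights)


def uniform_clique_triple(
    seed: int,
    n_genes: int = 8,
    sigma: float = 0.8,
) -> tuple[tuple[Genome, Genome, Genome], SimilarityGraph]:
    """A triple whose similarity graph is disjoint uniform-weight 3-cliques.

    Gene k of each genome belongs to clique k; orders are independent random
    signed permutations.  On such instances no conflicts exist and the
    family-free median coincides with the classical mixed multichromosomal
    breakpoint median, solvable by maximum-weight matching alone.
    """
    rng = np.random.default_rng(seed)
    genomes = []
    for gid in ("G", "H", "I"):
        order = [
            (int(rng.choice([-1, 1])), f"{gid.lower()}{k}") for k in range(n_genes)
        ]
        perm = rng.permutation(n_genes)
        order = [order[int(j)] for j in perm]
        genomes.append(Genome.from_orders(gid, [("c1", LINEAR, order)]))
    weights: dict[frozenset, float] = {}
    for k in range(n_genes):
        trio = [genome.gene(f"{genome.id.lower()}{k}") for genome in genomes]
        for ai in range(3):
            for bi in range(ai + 1, 3):
                weights[frozenset({trio[ai], trio[bi]})] = sigma
    return tuple(genomes), SimilarityGraph(tuple(genomes), weights)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionRecall:
    precision: float | None  # None when nothing was predicted (0/0)
    recall: float | None
    n_true_positive: int = 0
    n_predicted: int = 0
    n_true: int = 0


def _inter_genome_pairs(group: Iterable[tuple[str, str]]) -> set[frozenset]:
    members = sorted(set(group))
    return {
        frozenset({a, b})
        for ai, a in enumerate(members)
        for b in members[ai + 1 :]
        if a[0] != b[0]
    }


def precision_recall(
    components: Iterable[Iterable[tuple[str, str]]], truth: TruthTable
) -> PrecisionRecall:
    """Precision/recall over inter-genome gene pairs co-occurring in a
    predicted component; 0/0 is reported as None, not 1."""
    predicted: set[frozenset] = set()
    for comp in components:
        predicted |= _inter_genome_pairs(comp)
    true = set(truth.true_pairs)
    tp = len(predicted & true)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(true) if true else None
    return PrecisionRecall(precision, recall, tp, len(predicted), len(true))


def classify_groups(
    groups: Iterable[Iterable[tuple[str, str]]],
    families: Mapping[tuple[str, str], object],
) -> dict[str, int]:
    """Classify predicted ortholog groups against reference families.

    A group *agrees* if all members lie in one family.  It *disagrees* if two
    members x (genome X) and y (genome Y) lie in different families and x's
    family contains another gene of genome Y.  Otherwise it is *compatible*.
    """
    members_of: dict[object, set[tuple[str, str]]] = {}
    for gene, fam in families.items():
        members_of.setdefault(fam, set()).add(gene)

    counts = {"agree": 0, "compatible": 0, "disagree": 0}
    for group in groups:
        group = sorted(set(group))
        fams = {families.get(g) for g in group}
        if len(fams) == 1 and None not in fams:
            counts["agree"] += 1
            continue
        disagree = False
        for x in group:
            fx = families.get(x)
            if fx is None:
                continue
            for y in group:
                fy = families.get(y)
                if fy is None or y[0] == x[0] or fx == fy:
                    continue
                # does x's family contain another gene of y's genome?
                if any(m[0] == y[0] and m != y for m in members_of[fx]):
                    disagree = True
                    break
            if disagree:
                break
        counts["disagree" if disagree else "compatible"] += 1
    return counts


def fragility(
    groupings: Sequence[Iterable[Iterable[tuple[str, str]]]],
    genome_x: str,
    genome_y: str,
) -> int:
    """Number of fragile pairs across groupings that share genomes X and Y.

    A pair (x, y) is fragile iff it is co-grouped in at least one grouping
    and not co-grouped in at least one other.
    """
    per_run: list[set[frozenset]] = []
    for groups in groupings:
        pairs: set[frozenset] = set()
        for comp in groups:
            pairs |= {
                p
                for p in _inter_genome_pairs(comp)
                if {gid for gid, _g in p} == {genome_x, genome_y}
            }
        per_run.append(pairs)
    n = len(per_run)
    seen: dict[frozenset, int] = {}
    for pairs in per_run:
        for p in pairs:
            seen[p] = seen.get(p, 0) + 1
    return sum(1 for count in seen.values() if 0 < count < n)


# ---------------------------------------------------------------------------
# truth table I/O
# ---------------------------------------------------------------------------

def write_truth(truth: TruthTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene_id in sorted(truth.lineage):
            gid, anc, positional, n_dups = truth.lineage[gene_id]
            fh.write(f"{gene_id}\t{gid}\t{anc}\t{int(positional)}\t{n_dups}\n")


def read_truth(path: str | Path) -> TruthTable:
    lineage: dict[str, tuple[str, int, bool, int]] = {}
    with Path(path).open() as fh:
        for line in fh:
            gene_id, gid, anc, positional, n_dups = line.rstrip("\n").split("\t")
            lineage[gene_id] = (gid, int(anc), bool(int(positional)), int(n_dups))
    by_anc: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for gene_id, (gid, anc, positional, _nd) in lineage.items():
        if positional:
            by_anc.setdefault(anc, []).append((gid, gene_id))
    true_pairs = set()
    for members in by_anc.values():
        for ai, a in enumerate(members):
            for b in members[ai + 1 :]:
                if a[0] != b[0]:
                    true_pairs.add(frozenset({a, b}))
    return TruthTable(lineage, frozenset(true_pairs))
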