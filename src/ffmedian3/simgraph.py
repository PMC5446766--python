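"""Tripartite gene similarity graph and its construction from BLAST-like hits.

The family-free framework replaces gene-family assignments by a symmetric
similarity measure sigma > 0 over inter-genome gene pairs.  This module builds
that measure either directly from a sigma table or from tabular BLAST hits
via two preprocessing steps:

* a *stringency filter* with local threshold f: a hit g -> h is kept iff its
  bit-score is at least f times the best bit-score of any hit from h to a
  gene of g's genome;
* *relative reciprocal BLAST score* (RRBS) weighting: bit-scores of the two
  directions normalized by the self-hit scores, yielding sigma in (0, 1] for
  ordinary bit-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .genomes_io import Gene, Genome


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class BlastHit:
    """One row of a 12-column tabular (outfmt-6-like) hit file."""

    query: str
    subject: str
    bitscore: float
    extras: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise SimilarityError(
                f"negative bit-score for hit {self.query}->{self.subject}"
            )


class SimilarityGraph:
    """Weighted tripartite graph over the genes of three genomes.

    Invariants: weights strictly positive, only inter-genome edges, no edges
    incident to telomeres, sigma symmetric (stored once per unordered pair).
    """

    def __init__(
        self,
        genomes: tuple[Genome, Genome, Genome],
        weights: Mapping[frozenset, float],
    ):
        if len({g.id for g in genomes}) != 3:
            raise SimilarityError("three distinct genomes required")
        self.genomes = tuple(genomes)
        self.by_id = {g.id: g for g in genomes}
        self._sigma: dict[frozenset, float] = {}
        self._neighbours: dict[Gene, dict[str, list[Gene]]] = {}
        for pair, sigma in weights.items():
            genes = tuple(pair)
            if len(genes) != 2:
                raise SimilarityError(f"malformed edge {pair!r}")
            x, y = genes
            if x.genome_id == y.genome_id:
                raise SimilarityError(f"intra-genome edge {x!r} -- {y!r}")
            if x.is_telomere or y.is_telomere:
                raise SimilarityError(f"edge incident to a telomere: {x!r} -- {y!r}")
            if sigma <= 0:
                raise SimilarityError(f"non-positive sigma for {x!r} -- {y!r}")
            for g in (x, y):
                if g.genome_id not in self.by_id or g not in self.by_id[g.genome_id]:
                    raise SimilarityError(f"gene {g!r} not in any input genome")
            self._sigma[frozenset(pair)] = float(sigma)
        for pair in self._sigma:
            x, y = tuple(pair)
            self._neighbours.setdefault(x, {}).setdefault(y.genome_id, []).append(y)
            self._neighbours.setdefault(y, {}).setdefault(x.genome_id, []).append(x)
        for nbrs in self._neighbours.values():
            for lst in nbrs.values():
                lst.sort()

    def sigma(self, x: Gene, y: Gene) -> float:
        """sigma(x, y); 0 when no edge is present."""
        return self._sigma.get(frozenset({x, y}), 0.0)

    def edges(self) -> list[tuple[Gene, Gene, float]]:
        """All edges, deterministically sorted, with x < y."""
        out = []
        for pair, s in self._sigma.items():
            x, y = sorted(pair)
            out.append((x, y, s))
        out.sort()
        return out

    def neighbours(self, x: Gene, genome_id: str) -> list[Gene]:
        """Genes of ``genome_id`` connected to ``x`` (sorted)."""
        return self._neighbours.get(x, {}).get(genome_id, [])

    @property
    def n_edges(self) -> int:
        return len(self._sigma)

    def __repr__(self) -> str:
        ids = ",".join(g.id for g in self.genomes)
        return f"SimilarityGraph([{ids}], {self.n_edges} edges)"


# ---------------------------------------------------------------------------
# BLAST tabular input
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column tab-separated hits; bit-score is the last column."""
    hits = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise SimilarityError(
                    f"{path}:{lineno}: expected 12 columns, found {len(cols)}"
                )
            try:
                bitscore = float(cols[11])
            except ValueError as exc:
                raise SimilarityError(
                    f"{path}:{lineno}: malformed bit-score {cols[11]!r}"
                ) from exc
            hits.append(BlastHit(cols[0], cols[1], bitscore, tuple(cols[2:11])))
    return hits


def stringency_filter(
    hits: Iterable[BlastHit], f: float, genome_of: Mapping[str, str]
) -> list[BlastHit]:
    """Keep inter-genome hits passing the local bit-score threshold.

    A hit g -> h survives iff bit(g, h) >= f * max_{g' in genome(g)} bit(h, g').
    Self and intra-genome hits are dropped from the output (they remain
    available to the caller, e.g. for RRBS normalization).
    """
    if not 0 <= f <= 1:
        raise ValueError(f"stringency parameter f={f} outside [0, 1]")
    hits = list(hits)
    for hit in hits:
        for g in (hit.query, hit.subject):
            if g not in genome_of:
                raise SimilarityError(f"gene {g!r} has no genome assignment")
    # best[(h, X)] = best bit-score of a hit from h to any gene of genome X
    best: dict[tuple[str, str], float] = {}
    for hit in hits:
        key = (hit.query, genome_of[hit.subject])
        if hit.bitscore > best.get(key, 0.0):
            best[key] = hit.bitscore
    kept = []
    for hit in hits:
        g, h = hit.query, hit.subject
        if genome_of[g] == genome_of[h]:
            continue
        threshold = f * best.get((h, genome_of[g]), 0.0)
        if hit.bitscore >= threshold:
            kept.append(hit)
    return kept


def rrbs_weights(
    hits_filtered: Iterable[BlastHit],
    hits_all: Iterable[BlastHit],
    genomes: tuple[Genome, Genome, Genome],
    normalization: str = "sum",
) -> SimilarityGraph:
    """Relative reciprocal BLAST score weighting of filtered hits.

    With both directions surviving the filter::

        sigma(g, h) = (bit(g,h) + bit(h,g)) / (bit(g,g) + bit(h,h))

    and a single surviving direction contributes 2*bit(g,h)/(bit(g,g)+bit(h,h)).
    ``normalization='mean'`` averages the per-direction ratios
    bit(g,h)/bit(g,g) instead (exact published form of RRBS differs between
    sources; both preserve symmetry and sigma in (0, 1] for true bit-scores).
    """
    if normalization not in ("sum", "mean"):
        raise ValueError(f"unknown RRBS normalization {normalization!r}")
    self_score: dict[str, float] = {}
    for hit in hits_all:
        if hit.query == hit.subject:
            self_score[hit.query] = max(self_score.get(hit.query, 0.0), hit.bitscore)

    directed: dict[tuple[str, str], float] = {}
    for hit in hits_filtered:
        key = (hit.query, hit.subject)
        directed[key] = max(directed.get(key, 0.0), hit.bitscore)

    by_id: dict[str, Gene] = {}
    for genome in genomes:
        for gene in genome.non_telomeric_genes():
            by_id[gene.id] = gene

    weights: dict[frozenset, float] = {}
    for (g, h), bit_gh in sorted(directed.items()):
        if g not in by_id or h not in by_id:
            raise SimilarityError(f"hit references unknown gene in {g!r}->{h!r}")
        for x in (g, h):
            if x not in self_score:
                raise SimilarityError(f"missing self-hit for gene {x!r}")
        bit_hg = directed.get((h, g))
        if normalization == "sum":
            denom = self_score[g] + self_score[h]
            if bit_hg is not None:
                sigma = (bit_gh + bit_hg) / denom
            else:
                sigma = 2.0 * bit_gh / denom
        else:  # mean of per-direction relative scores
            if bit_hg is not None:
                sigma = 0.5 * (bit_gh / self_score[g] + bit_hg / self_score[h])
            else:
                sigma = bit_gh / self_score[g]
        pair = frozenset({by_id[g], by_id[h]})
        if sigma > 0:
            weights[pair] = max(weights.get(pair, 0.0), sigma)
    return SimilarityGraph(genomes, weights)


# ---------------------------------------------------------------------------
# sigma table input
# ---------------------------------------------------------------------------

def read_sigma_table(
    path: str | Path, genomes: tuple[Genome, Genome, Genome]
) -> SimilarityGraph:
    """Read a TSV ``gene_a<TAB>gene_b<TAB>sigma`` table; symmetrize by max."""
    by_id: dict[str, Gene] = {}
    for genome in genomes:
        for gene in genome.non_telomeric_genes():
            by_id[gene.id] = gene
    weights: dict[frozenset, float] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise SimilarityError(
                    f"{path}:{lineno}: expected 3 columns, found {len(cols)}"
                )
            a, b, raw_sigma = cols
            try:
                sigma = float(raw_sigma)
            except ValueError as exc:
                raise SimilarityError(
                    f"{path}:{lineno}: malformed sigma {raw_sigma!r}"
                ) from exc
            if sigma <= 0:
                raise SimilarityError(
                    f"{path}:{lineno}: non-positive sigma for {a!r} -- {b!r}"
                )
            if a not in by_id or b not in by_id:
                raise SimilarityError(f"{path}:{lineno}: unknown gene in {a!r}/{b!r}")
            pair = frozenset({by_id[a], by_id[b]})
            weights[pair] = max(weights.get(pair, 0.0), sigma)
    return SimilarityGraph(genomes, weights)


def write_sigma_table(graph: SimilarityGraph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for x, y, s in graph.edges():
            fh.write(f"{x.id}\t{y.id}\t{s:.10g}\n")
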