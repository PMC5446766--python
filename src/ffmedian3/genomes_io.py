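"""Genome data model and plain-text readers/writers.

A genome is a set of genes together with a set of adjacencies between gene
*extremities*.  Every ordinary gene ``g`` has two extremities, a tail ``g^t``
and a head ``g^h``; the ends of linear chromosomes are modelled explicitly by
telomere pseudo-genes with a single (telomeric) extremity.  Two extremities
form an adjacency when they are immediate neighbours in the chromosome
sequence: a gene read in forward orientation exposes its tail to the left
neighbour and its head to the right neighbour, reverse orientation swaps the
two.

The on-disk genome format is order-based plain text::

    #chromosome <name> linear|circular
    +geneA
    -geneB
    ...

Telomeres are never read from files; they are synthesized for linear
chromosomes with the reserved ids ``<chrom>:TL`` and ``<chrom>:TR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

HEAD = "h"
TAIL = "t"
TELOMERIC = "o"

LINEAR = "linear"
CIRCULAR = "circular"


class GenomeFormatError(ValueError):
    """Raised on malformed genome files or inconsistent genome construction."""


@dataclass(frozen=True, order=True)
class Gene:
    """A gene (or telomere pseudo-gene) of one genome.

    Identity is the ``(genome_id, id)`` pair; positional information lives in
    the owning :class:`Genome`, so gene objects stay valid across the
    gene-content filtering steps used by the median pipeline.
    """

    genome_id: str
    id: str
    is_telomere: bool = field(default=False, compare=False)

    @property
    def head(self) -> "Extremity":
        return Extremity(self, HEAD)

    @property
    def tail(self) -> "Extremity":
        return Extremity(self, TAIL)

    @property
    def extremities(self) -> tuple["Extremity", ...]:
        if self.is_telomere:
            return (Extremity(self, TELOMERIC),)
        return (Extremity(self, TAIL), Extremity(self, HEAD))

    def __repr__(self) -> str:  # compact, used in error messages
        return f"{self.genome_id}:{self.id}"


@dataclass(frozen=True, order=True)
class Extremity:
    gene: Gene
    side: str  # HEAD, TAIL or TELOMERIC

    def __post_init__(self) -> None:
        if self.side not in (HEAD, TAIL, TELOMERIC):
            raise ValueError(f"invalid extremity side {self.side!r}")
        if (self.side == TELOMERIC) != self.gene.is_telomere:
            raise ValueError(
                f"side {self.side!r} inconsistent with telomere flag of {self.gene!r}"
            )

    def __repr__(self) -> str:
        return f"{self.gene!r}^{self.side}"


#: An adjacency is an unordered pair of extremities of one genome.
Adjacency = frozenset


def _left_extremity(gene: Gene, sign: int) -> Extremity:
    return Extremity(gene, TAIL if sign > 0 else HEAD)


def _right_extremity(gene: Gene, sign: int) -> Extremity:
    return Extremity(gene, HEAD if sign > 0 else TAIL)


@dataclass(frozen=True)
class Chromosome:
    name: str
    topology: str  # LINEAR or CIRCULAR
    order: tuple[tuple[Gene, int], ...]  # signed gene order, signs in {+1, -1}

    def __post_init__(self) -> None:
        if self.topology not in (LINEAR, CIRCULAR):
            raise GenomeFormatError(f"unknown topology {self.topology!r}")


class Genome:
    """Signed gene orders on linear/circular chromosomes.

    Derived views: :attr:`genes` (including synthesized telomeres),
    :attr:`adjacencies`, and position lookup via :meth:`position`.
    """

    def __init__(self, genome_id: str, chromosomes: Sequence[Chromosome]):
        self.id = genome_id
        self.chromosomes = tuple(chromosomes)
        self._genes: dict[str, Gene] = {}
        self._telomeres: list[Gene] = []
        self._position: dict[Gene, tuple[int, int]] = {}
        self._sign: dict[Gene, int] = {}
        adjacencies: set[Adjacency] = set()

        for ci, chrom in enumerate(self.chromosomes):
            for pos, (gene, sign) in enumerate(chrom.order):
                if gene.genome_id != genome_id:
                    raise GenomeFormatError(
                        f"gene {gene!r} does not belong to genome {genome_id!r}"
                    )
                if gene.id in self._genes:
                    raise GenomeFormatError(
                        f"duplicate gene id {gene.id!r} in genome {genome_id!r}"
                    )
                self._genes[gene.id] = gene
                self._position[gene] = (ci, pos)
                self._sign[gene] = sign

            n = len(chrom.order)
            if chrom.topology == LINEAR:
                tl = Gene(genome_id, f"{chrom.name}:TL", is_telomere=True)
                tr = Gene(genome_id, f"{chrom.name}:TR", is_telomere=True)
                for t in (tl, tr):
                    if t.id in self._genes:
                        raise GenomeFormatError(
                            f"reserved telomere id {t.id!r} clashes in {genome_id!r}"
                        )
                    self._genes[t.id] = t
                    self._telomeres.append(t)
                self._position[tl] = (ci, -1)
                self._position[tr] = (ci, n)
                if n == 0:
                    adjacencies.add(frozenset({tl.extremities[0], tr.extremities[0]}))
                else:
                    g0, s0 = chrom.order[0]
                    gn, sn = chrom.order[-1]
                    adjacencies.add(
                        frozenset({tl.extremities[0], _left_extremity(g0, s0)})
                    )
                    adjacencies.add(
                        frozenset({_right_extremity(gn, sn), tr.extremities[0]})
                    )
                for k in range(n - 1):
                    ga, sa = chrom.order[k]
                    gb, sb = chrom.order[k + 1]
                    adjacencies.add(
                        frozenset({_right_extremity(ga, sa), _left_extremity(gb, sb)})
                    )
            else:  # circular: wrap around, no telomeres
                for k in range(n):
                    ga, sa = chrom.order[k]
                    gb, sb = chrom.order[(k + 1) % n]
                    # n == 1 yields the self-adjacency {g^h, g^t}
                    adjacencies.add(
                        frozenset({_right_extremity(ga, sa), _left_extremity(gb, sb)})
                    )

        self.adjacencies: frozenset[Adjacency] = frozenset(adjacencies)
        self._adjacent: dict[Extremity, Extremity] = {}
        for adj in self.adjacencies:
            e1, e2 = tuple(adj)
            self._adjacent[e1] = e2
            self._adjacent[e2] = e1

    # -- derived accessors -------------------------------------------------

    @property
    def genes(self) -> tuple[Gene, ...]:
        """All genes including telomeres, in deterministic (sorted) order."""
        return tuple(sorted(self._genes.values()))

    @property
    def gene_set(self) -> frozenset[Gene]:
        return frozenset(self._genes.values())

    @property
    def telomeres(self) -> tuple[Gene, ...]:
        return tuple(sorted(self._telomeres))

    def non_telomeric_genes(self) -> tuple[Gene, ...]:
        return tuple(g for g in self.genes if not g.is_telomere)

    def gene(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    def __contains__(self, gene: Gene) -> bool:
        return self._genes.get(gene.id) == gene

    def position(self, gene: Gene) -> tuple[int, int]:
        """(chromosome index, position); telomeres get -1 / len."""
        return self._position[gene]

    def sign(self, gene: Gene) -> int:
        return self._sign[gene]

    def neighbour_of(self, ext: Extremity) -> Extremity | None:
        """The extremity adjacent to ``ext``, or None (only possible at
        unflanked ends, which do not occur in well-formed genomes)."""
        return self._adjacent.get(ext)

    def restricted_to(self, keep: Iterable[Gene]) -> "Genome":
        """A copy of this genome with gene content restricted to ``keep``.

        Telomeres are re-synthesized; adjacencies are recomputed from the
        reduced order, so genes separated only by discarded genes become
        adjacent.  Chromosomes left without genes are dropped entirely.
        """
        keep_set = {g for g in keep if not g.is_telomere}
        chroms = []
        for chrom in self.chromosomes:
            order = tuple((g, s) for g, s in chrom.order if g in keep_set)
            if order:
                chroms.append(Chromosome(chrom.name, chrom.topology, order))
        return Genome(self.id, chroms)

    def __repr__(self) -> str:
        n = sum(len(c.order) for c in self.chromosomes)
        return f"Genome({self.id!r}, {len(self.chromosomes)} chromosomes, {n} genes)"

    # -- construction helpers ---------------------------------------------

    @classmethod
    def from_orders(
        cls,
        genome_id: str,
        chromosomes: Sequence[tuple[str, str, Sequence[tuple[int, str]]]],
    ) -> "Genome":
        """Build a genome from ``(name, topology, [(sign, gene_id), ...])``."""
        chroms = []
        for name, topology, order in chromosomes:
            chroms.append(
                Chromosome(
                    name,
                    topology,
                    tuple((Gene(genome_id, gid), sign) for sign, gid in order),
                )
            )
        return cls(genome_id, chroms)


def adjacency_indicator(X: Genome, e1: Extremity, e2: Extremity) -> int:
    """1 iff ``{e1, e2}`` is an adjacency of genome ``X``, else 0."""
    for e in (e1, e2):
        if e.gene.genome_id != X.id or e.gene not in X:
            raise ValueError(f"extremity {e!r} does not belong to genome {X.id!r}")
    return int(frozenset({e1, e2}) in X.adjacencies)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, genome_id: str) -> Genome:
    """Read a genome from the plain-text order format (see module docstring)."""
    path = Path(path)
    chroms: list[tuple[str, str, list[tuple[int, str]]]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#chromosome"):
                parts = line.split()
                if len(parts) != 3:
                    raise GenomeFormatError(
                        f"{path}:{lineno}: malformed chromosome header {line!r}"
                    )
                _, name, topology = parts
                if topology not in (LINEAR, CIRCULAR):
                    raise GenomeFormatError(
                        f"{path}:{lineno}: unknown topology {topology!r}"
                    )
                chroms.append((name, topology, []))
            elif line.startswith("#"):
                continue  # comment
            else:
                if not chroms:
                    raise GenomeFormatError(
                        f"{path}:{lineno}: gene line before any chromosome header"
                    )
                sign = 1
                gid = line
                if line[0] in "+-":
                    sign = 1 if line[0] == "+" else -1
                    gid = line[1:].strip()
                if not gid:
                    raise GenomeFormatError(f"{path}:{lineno}: empty gene id")
                if gid in seen:
                    raise GenomeFormatError(
                        f"{path}:{lineno}: duplicate gene id {gid!r}"
                    )
                seen.add(gid)
                chroms[-1][2].append((sign, gid))
    return Genome.from_orders(genome_id, chroms)


def write_genome(genome: Genome, path: str | Path) -> None:
    """Write a genome in the plain-text order format (round-trips exactly)."""
    with Path(path).open("w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f"#chromosome {chrom.name} {chrom.topology}\n")
            for gene, sign in chrom.order:
                fh.write(f"{'+' if sign > 0 else '-'}{gene.id}\n")


def write_matching(
    components: Iterable[Iterable[tuple[str, str]]], path: str | Path
) -> None:
    """Write ortholog groups as TSV: component id, then ``genome:gene`` members.

    Output is deterministic: members sorted within groups, groups sorted by
    their member lists.
    """
    rows = sorted(sorted(set(comp)) for comp in components)
    with Path(path).open("w") as fh:
        for k, comp in enumerate(rows):
            members = "\t".join(f"{gid}:{g}" for gid, g in comp)
            fh.write(f"{k}\t{members}\n")


def read_matching(path: str | Path) -> list[list[tuple[str, str]]]:
    comps = []
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            comp = []
            for member in parts[1:]:
                gid, _, g = member.partition(":")
                comp.append((gid, g))
            comps.append(comp)
    return comps


def write_cars(
    cars: Iterable[tuple[bool, Sequence[tuple[int, tuple[str, str, str]]]]],
    path: str | Path,
) -> None:
    """Write CARs, one per line: signed ``(g,h,i)`` triples left-to-right,
    prefixed ``circular:`` for circular CARs."""
    with Path(path).open("w") as fh:
        for circular, elements in cars:
            body = " ".join(
                f"{'+' if sign > 0 else '-'}({g},{h},{i})"
                for sign, (g, h, i) in elements
            )
            prefix = "circular: " if circular else ""
            fh.write(f"{prefix}{body}\n")
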