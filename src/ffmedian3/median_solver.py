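"""Exact ILP for the family-free median of three, and CAR extraction.

The program uses two families of binary variables: a(m) for every candidate
median gene m (including telomere triples) and b(e) for every conserved
candidate median adjacency e, with

    maximize   sum_e w(e) * b(e)
    subject to (C.01)  sum_{m containing x} a(m) <= 1   for every extant gene
                                                         or telomere x,
               (C.02)  b(e) <= a(m1), b(e) <= a(m2)      for e = {m1^a, m2^b},
               (C.03)  sum_{e incident to m^a} b(e) <= 1 for every candidate
                                                         extremity m^a.

(C.01) makes the median conflict-free, (C.02) ties adjacencies to selected
genes, (C.03) makes the selected adjacency set a valid (partial) genome.

Models are solved with the HiGHS mixed-integer solver via
``scipy.optimize.milp``; the backend is deterministic, and models can be
emitted in LP format for audit.  The returned median contains only the
selected adjacencies and the candidates incident to them: unselected median
genes never increase the objective, and completing CARs into a capped genome
would add adjacencies unsupported by any extant genome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .genomes_io import HEAD, TAIL, Gene
from .median_model import (
    CandidateAdjacency,
    CandExtremity,
    FFMedianInstance,
    MedianCandidate,
    _ext_key,
)


class SolverError(RuntimeError):
    pass


@dataclass
class ILPModel:
    """A binary maximization program in row form (all rows are <= ub)."""

    var_names: list[str]
    objective: np.ndarray  # maximization coefficients
    rows: list[tuple[list[int], list[float], float]]  # (cols, coefs, ub)
    lower: np.ndarray  # per-variable lower bound (used to force variables)
    meta: dict = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return len(self.var_names)

    @property
    def n_constraints(self) -> int:
        return len(self.rows)

    def write_lp(self, path: str | Path) -> None:
        """Deterministic LP-format emission for audit."""
        with Path(path).open("w") as fh:
            fh.write("Maximize\n obj:")
            for j, c in enumerate(self.objective):
                if c:
                    fh.write(f" {'+' if c > 0 else '-'} {abs(c):.12g} {self.var_names[j]}")
            fh.write("\nSubject To\n")
            for r, (cols, coefs, ub) in enumerate(self.rows):
                terms = " ".join(
                    f"{'+' if c > 0 else '-'} {abs(c):.12g} {self.var_names[j]}"
                    for j, c in zip(cols, coefs)
                )
                fh.write(f" r{r}: {terms} <= {ub:.12g}\n")
            fh.write("Binary\n")
            for name in self.var_names:
                fh.write(f" {name}\n")
            fh.write("End\n")


def solve_milp(
    model: ILPModel, time_limit: float | None = None, seed: int = 0
) -> tuple[np.ndarray, str, float]:
    """Solve a binary maximization model; returns (x, status, objective).

    ``seed`` is accepted for interface uniformity; the HiGHS backend is
    deterministic so it has no effect.
    """
    n = model.n_variables
    if n == 0:
        return np.zeros(0), "optimal", 0.0
    constraints = []
    if model.rows:
        data, indices, indptr_rows = [], [], []
        ubs = []
        for cols, coefs, ub in model.rows:
            indptr_rows.append(len(data))
            data.extend(coefs)
            indices.extend(cols)
            ubs.append(ub)
        indptr_rows.append(len(data))
        A = sparse.csr_matrix(
            (data, indices, indptr_rows), shape=(len(model.rows), n)
        )
        constraints.append(
            LinearConstraint(A, -np.inf * np.ones(len(ubs)), np.asarray(ubs))
        )
    res = milp(
        c=-model.objective,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(model.lower, np.ones(n)),
        options={} if time_limit is None else {"time_limit": float(time_limit)},
    )
    if res.status == 0:
        status = "optimal"
    elif res.status == 1 and res.x is not None:
        status = "feasible"  # hit time/iteration limit with an incumbent
    elif res.status == 2:
        raise SolverError("model reported infeasible")
    else:
        raise SolverError(f"solver failed: {res.message}")
    x = np.round(res.x).astype(int)
    return x, status, float(-res.fun) if res.fun is not None else 0.0


# ---------------------------------------------------------------------------
# FF-Median model
# ---------------------------------------------------------------------------

def build_ffmedian_ilp(instance: FFMedianInstance) -> ILPModel:
    if not instance.candidates:
        warnings.warn("empty candidate set: trivial FF-Median model")
    cand_index = {m: j for j, m in enumerate(instance.candidates)}
    nc = len(instance.candidates)
    var_names = [f"a_{m.g.id}_{m.h.id}_{m.i.id}" for m in instance.candidates]
    var_names += [f"b_{k}" for k in range(len(instance.adjacencies))]
    n = nc + len(instance.adjacencies)
    objective = np.zeros(n)
    rows: list[tuple[list[int], list[float], float]] = []

    # C.01: each extant gene/telomere in at most one selected candidate
    for gene in sorted(instance.by_gene):
        members = instance.by_gene[gene]
        if len(members) >= 2:
            rows.append(([cand_index[m] for m in members], [1.0] * len(members), 1.0))

    by_ext: dict[CandExtremity, list[int]] = {}
    for k, adj in enumerate(instance.adjacencies):
        bj = nc + k
        objective[bj] = adj.weight
        # C.02: adjacency only between selected candidates
        for m, _side in adj.ends:
            rows.append(([bj, cand_index[m]], [1.0, -1.0], 0.0))
        for end in adj.ends:
            by_ext.setdefault(end, []).append(bj)

    # C.03: each candidate extremity in at most one adjacency
    for end in sorted(by_ext, key=_ext_key):
        cols = by_ext[end]
        if len(cols) >= 2:
            rows.append((cols, [1.0] * len(cols), 1.0))

    return ILPModel(
        var_names,
        objective,
        rows,
        np.zeros(n),
        meta={"kind": "ff-median", "n_candidates": nc,
              "n_adjacencies": len(instance.adjacencies)},
    )


@dataclass
class CAR:
    """A contiguous ancestral region: ordered, signed median candidates."""

    circular: bool
    elements: list[tuple[int, MedianCandidate]]  # (sign, candidate), telomeres excluded
    capped_left: bool = False
    capped_right: bool = False

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class Median:
    """A solved FF-Median: selected candidates/adjacencies and the objective."""

    candidates: list[MedianCandidate]
    adjacencies: list[CandidateAdjacency]
    objective: float
    status: str
    model_stats: dict = field(default_factory=dict)

    @property
    def cars(self) -> list[CAR]:
        return median_to_cars(self)

    def validate(self) -> None:
        """Assert conflict-freeness and extremity degree <= 1."""
        seen_genes: dict[Gene, MedianCandidate] = {}
        for m in self.candidates:
            for gene in m.genes:
                if seen_genes.setdefault(gene, m) != m:
                    raise AssertionError(f"conflict on extant gene {gene!r}")
        degree: dict[CandExtremity, int] = {}
        for adj in self.adjacencies:
            for end in adj.ends:
                degree[end] = degree.get(end, 0) + 1
                if degree[end] > 1:
                    raise AssertionError(f"extremity {end} in two adjacencies")
        recomputed = sum(adj.weight for adj in self.adjacencies)
        if not math.isclose(recomputed, self.objective, rel_tol=1e-6, abs_tol=1e-6):
            raise AssertionError(
                f"objective {self.objective} != sum of weights {recomputed}"
            )


def solve(
    model: ILPModel,
    instance: FFMedianInstance,
    time_limit: float | None = None,
    seed: int = 0,
) -> Median:
    """Solve an FF-Median model and assemble the median.

    Candidates that end up in no selected adjacency are dropped from the
    output (they cannot increase the objective).
    """
    x, status, _obj = solve_milp(model, time_limit=time_limit, seed=seed)
    nc = model.meta["n_candidates"]
    selected_adjs = [
        adj for k, adj in enumerate(instance.adjacencies) if x[nc + k] > 0
    ]
    used = {m for adj in selected_adjs for m in adj.candidates}
    candidates = sorted(used)
    objective = sum(adj.weight for adj in selected_adjs)
    median = Median(
        candidates,
        selected_adjs,
        objective,
        status,
        model_stats={
            "n_variables": model.n_variables,
            "n_constraints": model.n_constraints,
            **instance.stats,
        },
    )
    median.validate()
    return median


def solve_ffmedian(
    instance: FFMedianInstance,
    time_limit: float | None = None,
    seed: int = 0,
) -> Median:
    """Convenience: build and solve the FF-Median ILP for an instance."""
    model = build_ffmedian_ilp(instance)
    return solve(model, instance, time_limit=time_limit, seed=seed)


def median_to_cars(median: Median) -> list[CAR]:
    """Decompose selected adjacencies into linear and circular CARs.

    Path components become linear CARs (capped where telomere triples were
    selected); cycle components are flagged circular.  The element sign
    records whether a candidate is traversed tail-to-head (+) or head-to-tail
    (-) along the CAR.
    """
    neighbour: dict[CandExtremity, CandExtremity] = {}
    degree: dict[MedianCandidate, int] = {}
    for adj in median.adjacencies:
        e1, e2 = adj.ends
        neighbour[e1] = e2
        neighbour[e2] = e1
        for end in (e1, e2):
            degree[end[0]] = degree.get(end[0], 0) + 1

    cars: list[CAR] = []
    visited: set[MedianCandidate] = set()

    # path components start at degree-1 candidates (telomeres always are)
    for m in sorted(m for m, d in degree.items() if d == 1):
        if m in visited:
            continue
        visited.add(m)
        elements: list[tuple[int, MedianCandidate]] = []
        capped_l = capped_r = False
        matched_side = next(s for s in m.sides if (m, s) in neighbour)
        if m.is_telomeric:
            capped_l = True
        else:
            # leaving through the head means forward orientation
            elements.append((1 if matched_side == HEAD else -1, m))
        ext = neighbour[(m, matched_side)]
        while True:
            mm, side = ext  # entering mm at `side`
            visited.add(mm)
            if mm.is_telomeric:
                capped_r = True
                break
            elements.append((1 if side == TAIL else -1, mm))
            exit_ext = (mm, HEAD if side == TAIL else TAIL)
            if exit_ext not in neighbour:
                break
            ext = neighbour[exit_ext]
        if elements:
            cars.append(CAR(False, elements, capped_left=capped_l, capped_right=capped_r))

    # every remaining candidate has degree 2: cycle components
    for m in sorted(degree):
        if m in visited:
            continue
        visited.add(m)
        elements = [(1, m)]
        ext = neighbour[(m, HEAD)]
        while ext[0] != m:
            mm, side = ext
            visited.add(mm)
            elements.append((1 if side == TAIL else -1, mm))
            ext = neighbour[(mm, HEAD if side == TAIL else TAIL)]
        cars.append(CAR(True, elements))

    cars.sort(key=lambda car: car.elements[0][1].key if car.elements else ())
    return cars
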