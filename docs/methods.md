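# Methods

This note documents the models implemented in `ffmedian3`, the design
choices made where the published problem statements leave room, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## Genome model

Genomes are signed gene orders on linear or circular chromosomes.  A gene
exposes a tail to its left neighbour and a head to its right neighbour when
read forward; a reversed gene swaps the two.  Telomeres are explicit
pseudo-genes with a single extremity, synthesized for linear chromosomes
(ids `<chrom>:TL` / `<chrom>:TR`), never read from input.  The input format
is order-based (no coordinates), which avoids any 0/1-based ambiguity.
Although classical breakpoint-median expositions often omit orientation,
the head/tail extremity model requires it; unsigned input degrades
gracefully (all genes default to forward).

## FF-Median instance construction

* **Candidates** are exactly the tripartite triangles of the similarity
  graph: a triple with any zero pairwise similarity can never contribute a
  positive adjacency score, so nothing is lost.  The candidate score is the
  geometric mean of its three pairwise similarities.
* **Gene-content filtering.**  Genes outside every 3-clique cannot occur in
  any median; by default they are removed from the extant orders *before*
  adjacency extraction, so that adjacencies disrupted by, e.g., mobile-element
  insertions are restored.  `keep_unsupported=True` disables this.
  Chromosomes emptied by the filter are dropped entirely.
* **Telomere triples.**  The similarity of two telomeres is fixed to
  σ(∘,∘) := 1, so adjacency scores specialize cleanly to capped
  adjacencies.  One candidate telomere triple is formed per combination of
  one telomere per genome, but only triples that support at least one
  conserved candidate adjacency are kept — with few chromosomes this is a
  handful of triples, and it keeps the ILP small.  Telomeric candidate
  adjacencies carry the full weight of the adjacency-score formula; no
  extra halving convention (as used in some matching formulations of the
  classical median) is applied, because the objective already defines the
  weight.
* **Conserved adjacencies** are enumerated by scanning extant adjacencies
  and lifting them to candidate-extremity pairs, so only adjacencies
  present in at least one genome (weight > 0) are materialized; pairs of
  conflicting candidates are never emitted.

## The FF-Median ILP

Binary a(m) per candidate, b(e) per conserved candidate adjacency;
maximize Σ w(e)·b(e) subject to (C.01) each extant gene or telomere in at
most one selected candidate, (C.02) b(e) ≤ a(m) for both incident
candidates, (C.03) each candidate extremity in at most one selected
adjacency.  Models are solved with HiGHS through `scipy.optimize.milp`
behind a thin, replaceable layer; HiGHS is deterministic, so the `seed`
argument exists only for interface uniformity.  Models can be written in LP
format for audit.

The returned median contains only selected adjacencies and the candidates
incident to them: unselected candidates cannot change the objective, and
completing the CARs into a fully capped genome would require adjacencies
unsupported by any extant genome, which we consider dubious and do not
emit.  The objective is re-audited as the sum of recomputed adjacency
weights, and conflict-freeness and extremity degrees are asserted on every
solution.

## ICF-SEG preprocessing

A *run* is a chain of candidates that is conflict-free and whose
projections are consecutive in all three genomes with order and orientation
conserved up to a full reversal.  Orientation matters: the implementation
links two candidates only if the *same* extremity pair of the two genes is
an extant adjacency in all three genomes.  (A purely positional notion of
consecutiveness would accept transposed or re-oriented pairs, and a
maximum-weight matching over such a pseudo-run can fix a two-cycle that
destroys boundary adjacencies — observed in testing, hence the stricter
rule.)  Chains are grown only through unambiguous links (unique successor
and unique predecessor) with constant per-genome direction; this is a
deliberate, conservative simplification — a missed run only costs ILP time,
never correctness.

For each run S, the matching graph Γ′(S) holds the run's extremities, its
internal candidate adjacencies, and one conflict edge {mʰ, mᵗ} per member
weighted w′(m): the maximum total *potential* of a conflict-free subset of
the candidates externally conflicting with m.  The potential Δ(m) is the
best incident adjacency weight per extremity, summed — an upper bound on
m's achievable contribution.  w′ is computed exhaustively for up to 12
conflicting candidates and otherwise falls back to the sum of all
potentials; an overestimate can only make the test reject a run, never fix
one wrongly, so safety is preserved (verified empirically by the
equivalence tests, which also exercise the fallback by forcing
`exact_limit=0`).  Zero-weight conflict edges are omitted: a matching using
one never beats the same matching without it, and omitting them avoids
spurious rejections on ties.

If the maximum-weight matching in Γ′(S) (computed exactly by a general-graph
matching on weights scaled to integers by 10⁹ to avoid float ties) contains
no conflict edge, the matched adjacencies are fixed; externally conflicting
candidates, run-internal adjacencies and adjacencies competing for matched
extremities are removed from the instance.  A failed run is retried on its
maximal proper prefix and suffix (the retry granularity is not canonical;
prefix/suffix retries are simple and keep the worklist linear).  Runs are
processed longest first; runs touching already fixed or removed candidates
are skipped.

## FFAdj-3G

Candidate adjacency sets A\*(X) contain all extremity pairs realizable in a
subgenome of X.  The full union is quadratic in genome size and explodes
the number of conflicting conserved adjacencies, so A\* is capped at
`gap_limit` skipped genes (default 2); gap 0 recovers 𝒜(X) exactly.  The
cap is a documented deviation that keeps exact solving tractable at desk
scale; the reported F_α is audited under the same cap.

The ILP uses c(x,y) per similarity edge, d(x) per gene, and e(...) per
conserved-adjacency quadruple (two edges between the same genome pair whose
endpoint extremities form gap adjacencies on both sides, with matching
sides).  Constraints: per gene and per other genome at most one saturated
edge, plus d ≥ c (C.01); for every edge pair {g,h}, {g,i} into two
different genomes, c(g,h) + c(g,i) + Σ_{i′≠i} c(h,i′) ≤ 2 and symmetrically
for i — the direct {h,i} edge is *not* part of these sums (C.02); and
e ≤ c for both edges plus e + d(z) ≤ 1 for every gene z strictly between
either pair of extremities (C.03).  d variables are not penalized in the
objective; maximization drives them down to the minimum consistent with
d ≥ c.  Validity of every returned matching (components of at most one
gene per genome; the seven legal component shapes) is asserted, and F_α is
recomputed from the matching by scanning the gene orders.

## FFAdj-AM

The heuristic fixes the median-implied matching (a triangle per median
gene; conflict-freeness of the median guarantees feasibility) and re-solves
FFAdj-3G over the *entire* graph with those variables forced, rather than
deleting the median subgraph — this way conserved adjacencies spanning
median-derived and newly added components are scored.  The solution is
checked to dominate the median-induced score; components are labelled by
provenance (median / ffadj).

## Brute-force oracles

Both problems have exhaustive reference solvers used as ground truth in
tests.  They share no code path with the ILPs: adjacency weights are
recomputed from raw σ and extant adjacency sets, FF-Adjacencies scores are
recomputed by scanning gene orders, and the searches are plain
branch-and-bound (FF-Median: over adjacency subsets with conflict and
degree checks) or exhaustive recursion over exactly the valid partial
3-matchings (FF-Adjacencies).  Hard size guards refuse instances beyond
exhaustive feasibility.

## Synthetic data

The generator evolves an ancestral genome independently along three
branches.  Per-branch event counts are Poisson(rate × distance);
inversions and transpositions act on geometric-length segments (mean 3),
duplications copy a gene to a random position (the copy loses positional
status and accumulates a penalty), losses delete a gene.  Similarities of
genes sharing an ancestral lineage decay exponentially with the sum of
branch distances (λ = 1.0 per unit) plus 0.5 per duplication on the path,
with Gaussian noise whose s.d. (0.05) scales with path length so that at
distance zero σ is exactly 1.  Two observation effects are modelled:
homologies below a detection threshold (0.05) are not reported, emulating
alignment searches that miss distant homologs, and spurious hits connect
random unrelated pairs at rate 5·10⁻⁴ per inter-genome gene pair.

Defaults — 200-gene single-chromosome genomes; rates per unit distance of
4 inversions, 2 transpositions, 2 duplications, 2 losses — represent a
scaled-down bacterial genome; distances are abstract units, not calibrated
to PAM, and no sequence-level evolution is simulated.  Ground truth labels
a pair of extant genes positional orthologs iff they descend from the same
ancestral gene and neither copy was displaced by a duplication.

What passing simulation tests show — and what they do not: the generator
produces the tripartite triangle signal, synteny conservation decaying with
divergence, paralogy confusion and missing/spurious edges that the methods
are designed for, so the observed trends (near-perfect precision, recall
declining with divergence, the FFAdj stage recovering pairs the median
cannot express) are meaningful.  It does not reproduce real alignment-score
distributions, rate heterogeneity across genes, operon structure, or
horizontal transfer; absolute precision/recall values on real data will
differ.

## Problem sizes and numerics

The test-suite and acceptance-script problem sizes (5-gene random triples
for FF-Median/oracle equivalence, 4-gene triples with gap ≤ 1 for
FFAdj-3G, 12-gene simulated triples for preprocessing safety, 200-gene
triples for the simulation trend) were chosen so that the exhaustive
oracles remain exact and the whole suite runs in minutes on one CPU; they
are the package's desk-scale study conditions, not statements about the
solvers' capacity (the ILPs handle bacterial-scale instances).

Objective comparisons use a relative/absolute tolerance of 10⁻⁶; matching
weights are integerized at 10⁹ before maximum-weight matching; ILP
variables are rounded before extraction.  Ties between optima are resolved
by the solver; tests compare objective values only.  Degenerate inputs —
empty similarity graphs, empty chromosomes after filtering, single-gene
circular chromosomes (self-adjacency {gʰ, gᵗ}) — are handled explicitly.

## Known limitations

* Runs (not general common intervals) are the only local structures
  exploited by the preprocessing.
* The FFAdj-3G gap cap excludes conserved adjacencies spanning more than
  `gap_limit` matched-away genes from the objective.
* k > 3 genomes are out of scope throughout.
* The two heuristic stages are run once, not iterated to convergence.
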