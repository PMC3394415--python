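# Methods

## Genome model

Genomes are circular signed permutations over a shared gene set {1..n}.
Gene *i* maps to extremity vertices 2i−1 (tail) and 2i (head); consecutive
genes g, h (with circular wrap) contribute the unordered extremity pair
joining the right end of g to the left end of h, so a genome is exactly a
perfect matching on {1..2n} with no (2i−1, 2i) edge.  Equality is circular:
a rotation, or the reflected all-signs-flipped rotation, denotes the same
genome.  The canonical form rotates gene 1 to the front with positive sign;
all comparisons, file output and accuracy counting go through it.

The only rearrangement operation modelled is the inversion: positions
i..j of the written order are reversed with all signs flipped.  Distance is
the DCJ cycle distance d = n − c, with c the number of alternating cycles
in the union of two matchings.  Multichromosomal events (translocation,
fission, fusion), unequal gene content and duplications are out of scope.

## Median solver

The median of three genomes minimizes the summed DCJ distance, equivalently
maximizes the total alternating-cycle count of one matching against three.
The solver is a depth-first branch and bound over perfect matchings with a
single-circle constraint: a fragment-endpoint table (`link`) tracks the
open path each live extremity terminates, and a median edge that would
close a chromosome before all 2n extremities are matched is never taken —
so every result is a valid circular genome, matching the brute-force oracle
that enumerates the (n−1)!·2^(n−1) canonical circular permutations.

Three devices make the search practical:

* **Adequate-pair contraction.**  A vertex pair joined by ≥ 2 parallel
  input edges closes ≥ 2 cycles when taken, meeting the 3m/2 threshold for
  a 2-vertex (m = 1) adequate subgraph; such pairs are committed and
  contracted eagerly, cascading as contraction creates new parallel edges.
  Under the single-circle constraint this commitment is heuristic in
  principle (the classical exchange argument can split the circle); it
  remained exact against brute force on every random triple tested
  (hundreds, n = 4–6, plus the 200-triple suite check), and a
  `commit_multiplicity=3` mode restricts commitment to unanimous
  adjacencies if stricter behavior is wanted.
* **Pairwise cycle bound.**  At a node with 2k live vertices and partial
  cycle count C, achievable total cycles are bounded by
  C + ⌊(3k + c₁₂ + c₁₃ + c₂₃)/2⌋, from the triangle inequality of the
  cycle distance on matchings (cᵢⱼ computed on the live residual graph).
  Admissibility is asserted against the brute-force optimum in the suite.
* **Greedy incumbent.**  One budget-free greedy dive (highest multiplicity
  first) plus any caller-supplied candidate genomes seed the incumbent, so
  pruning starts immediately and budget-exhausted calls still return a
  feasible, often good, median flagged `optimal=False`.  The default node
  budget is 10⁷; the experiment driver uses 5·10⁴, which at the benchmark
  rates is never reached (medians at 12% per edge typically solve during
  contraction, in a handful of nodes).

Adjacency fixing commits caller-specified edges by the same contraction
before the search starts, crediting a cycle per matching that already held
the edge; this is arithmetically identical to the published edge surgery
(remove (i, a), (j, b); add (i, j), (a, b)) followed by contraction of the
resulting 3-parallel pair, but keeps all cycle counts relative to the
*original* genomes so reported scores need no shift.  Branching order is
deterministic (lowest free vertex; partners by descending multiplicity,
ties by id), so results are reproducible; when several medians are
co-optimal the search keeps the first one found.

## Likelihood stage

Each candidate adjacency (any extremity pair observed in ≥ 1 leaf) evolves
independently as a two-state continuous-time Markov chain whose time is the
edge's expected event count.  An inversion breaks 2 of the n adjacencies of
a circular genome, giving a loss rate of 2/n per event; a re-formed
junction picks this particular partner among the 2n−3 available ends,
giving a gain rate of 2/(n(2n−3)).  The stationary presence probability is
therefore 1/(2n−2), used as the root prior, and the transition matrix is
the closed-form matrix exponential, which satisfies both anchor limits:
identity at t = 0 and convergence of every row to the stationary
distribution as t → ∞.  (A literal per-event survival power (1−2/n)^t with
a matched gain term has the same first-order behavior but is not a
semigroup and fails the infinite-length limit, which is why the CTMC
parametrization is used.)  Edge lengths are floored at 10⁻⁹ so zero-length
trees with conflicting leaves resolve by majority weighting rather than
0/0.

Posteriors come from standard pruning after rooting the tree at the target
node; treating adjacencies independently is an approximation — dependence
enters only at assembly.  Assembly is greedy maximum-probability matching:
candidates sorted by posterior (ties by vertex id), accepted when both
extremities are free and no premature circle forms, re-scanned to fixpoint
because the circle rule is order-dependent; stranded extremities (covered
by no candidate) are completed by lowest-id pairing with a logged warning.
When true per-edge rates are unknown, edge lengths are fitted to pairwise
leaf DCJ distances by nonnegative least squares; the benchmark driver uses
the simulator's true expected counts.

## Mixture pipeline

Per node and replicate, proposals with posterior > 0.9 are always fixed and
a uniform random sample of the remaining proposals tops the fixed set up to
⌊0.72·n⌉ (the middle of the workable 70–75% window; any subset of one
genome's matching is automatically compatible).  A constrained median of
the node's three neighbors is solved; every non-fixed proposal appearing in
its output gains a count, and eligibility (replicates where it was not
fixed) is tracked so frequently fixed proposals are not penalized — ranking
uses counts/eligible.  100 replicates are the default; the suite checks
that two independent 100-replicate rankings correlate at Spearman ρ ≥ 0.95.

The final median fixes the top selection-percentage fraction of proposals
(ties broken by posterior, then vertex id).  The selection percentage
defaults to 0.70 for closely related genomes and 0.75 when the per-edge
rate exceeds 24% of n or the tree diameter exceeds 3n, reflecting that at
high rates more likelihood proposals must be carried because the median
recovers fewer on its own; both are overridable.

Tree refinement initializes internal nodes with their likelihood
reconstruction (pure median mode: nearest leaf), then sweeps the internal
nodes, re-ranking and re-solving each against its current neighbors; an
update is accepted only when it strictly lowers the node's local score, so
the tree score is non-increasing and, being a nonnegative integer,
convergence is guaranteed; sweeps stop when a full sweep leaves the score
unchanged (cap 20).  Rankings are redone each sweep by default
(`rank_once` reuses the first table per node).  With a fixed seed the whole
pipeline is bit-reproducible; replicates are independent, so a parallel
driver would only need to reproduce the per-replicate seed sequence.

## Simulator

The study conditions the generator emulates: unrooted binary trees over 10
leaves with 100-gene circular genomes.  Topologies are uniform over
leaf-labelled unrooted binary trees (sequential uniform edge attachment).
Uniform model: per-edge expected inversion counts drawn uniformly in
[rn(1−f), rn(1+f)] with f = 0.5 (50% relative fluctuation), r the quoted
per-edge rate (12–36% of n in the benchmarks).  Lin–Moret-style model:
exponential edge weights rescaled so the largest leaf-to-leaf expected
path equals diameter·n (0.6–4.0 n) — a deliberately unbalanced-edge-length
stand-in for the original birth–death construction, isolated behind the
model flag.  Evolution applies round(weight) inversions per edge with
endpoints uniform over positions, starting from the identity genome at an
arbitrary internal root (accuracy is invariant to that choice).  The gene
count is a first-class parameter; 100 genes is the conventional scale in
this literature and all reported accuracies document it.

What the simulator does not emulate: transpositions or multichromosomal
events, indels/duplications, rate heterogeneity beyond the per-edge draw,
and any sequence-level signal.  Passing benchmarks therefore speak to
inversion-driven unichromosomal evolution, not to genomes where those
features matter.

## Evaluation and problem sizes

Adjacency accuracy is |adj(inferred) ∩ adj(truth)|/n, strand-aware by the
extremity encoding and invariant to canonicalization; experiment means are
unweighted over all internal nodes of all datasets.  The benchmark driver
(`scripts/acceptance.py` and the table-reproduction tests) runs 100-gene,
10-leaf configurations with 10 simulated datasets for the likelihood
quantities and 5 for the pure-median quantity — the package's chosen
desk-scale rendering of averages originally taken over 50 datasets; at
these sizes the between-seed spread of the reported means is well under a
percentage point for the median method and about one point for the
likelihood method.

## Known limitations

* The likelihood stage's accuracy at a given rate depends on the adjacency
  evolution model; the CTMC here is a deliberate simplification of richer
  rearrangement likelihoods, and its reconstructions at the benchmark
  rates run 1–3 accuracy points above the published likelihood baseline.
* At very high rates (≳ 40% of n per edge) too few likelihood proposals
  are correct for the fixing strategy to help, the same failure regime the
  mixture approach is known to have.
* Eager adequate-pair commitment under the single-circle constraint is
  empirically exact but not proven; `commit_multiplicity=3` trades speed
  for a weaker commitment rule, and the node budget bounds worst-case work
  either way.
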