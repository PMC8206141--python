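# Methods

## Flow-network model

The pipeline casts mediator discovery as minimum-cost flow on a
heterogeneous graph. Probabilistic edge confidences become arc costs via
`cost = −ln(weight)`, so a path's cost is the negative log of its
probability under an independence assumption across edges, and minimizing
cost prefers the jointly most probable drug→gene→…→disease routes. The
assumptions worth being explicit about:

- **Weights are treated as probabilities.** Drug–target and disease–gene
  scores are normalized per entity (they sum to 1 over a drug's targets or
  a disease's genes), which makes boundary arcs a probability distribution
  over entry/exit genes. Gene–gene linkage confidences, however, are
  log-likelihood-combined evidence scores and are unbounded above 1; they
  are mapped into (0, 1] by dividing by the global maximum. This preserves
  the ordering of confidences and gives the single best-supported
  interaction zero cost. Any monotone alternative (e.g. logistic
  calibration) can be applied upstream before the network is built.
- **Evidence combination.** Per-dataset log-likelihood scores are combined
  as `best + Σ_i rest_i/(D·i)` with `i = 1` at the second-best retained
  score. Scores below the threshold `T` are discarded entirely; if none
  remain the linkage has no evidence and no edge is created. `D` and `T`
  default to 2.0 and 1.0 and are exposed in the run configuration — they
  are dataset-calibration constants with no universal correct value, and
  most users will instead supply an already-integrated weighted network.
- **Antiparallel gene arcs.** Each undirected interactome edge becomes two
  independent directed arcs with capacity 1 each. No shared-capacity
  coupling is needed: carrying flow both ways simultaneously strictly
  raises cost at equal net transport whenever the arc cost is positive, so
  optimal solutions never do it (asserted as a test).

## The linear program

With one variable per arc, the objective
`Σ cost·F − γ·Σ F_source→v` under conservation at every interior node, a
source/sink balance constraint, and box bounds `0 ≤ F ≤ C` is a generic
bounded LP — the reward term takes it outside the classical min-cost-flow
framework, so it is solved exactly with the HiGHS dual-simplex method
(`scipy.optimize.linprog`). Zero flow is always feasible and costs are
non-negative, so the LP is never unbounded and γ has a clean reading: a
source→sink path carries flow iff γ exceeds its summed arc cost. Total
source out-flow is therefore non-decreasing in γ (an LP-duality fact), and
in practice so is the positive-arc count; both are exercised over a γ grid
in the tests. Defaults are γ = 6 for the drug-as-source context and γ = 8
for the disease-as-source context, both overridable.

Degenerate optima are possible (ties between equal-cost routes). The
solver returns one optimal basic solution; downstream consumers must not
depend on which vertex is chosen, and the determinism tests use generic
(continuous random) weights where ties have probability zero. Arcs are
declared flow-positive above ε = 1e-8, comfortably above the solver's
tolerance and below any meaningful flow at the capacity scales used.

## Decomposition, ranking, clustering

The per-association subnetwork is the set of arcs (u, v) with u reachable
from the source and the endpoint reachable from v inside the positive-flow
graph — exactly the union of all simple source→endpoint paths when that
graph is acyclic (which optimal solutions are, up to zero-cost ties), and
its natural generalization otherwise. A gene's rank score is its inbound
flow within the association's subnetwork; ties break lexicographically so
output is deterministic.

Markov clustering runs on the symmetrized gene–gene flow matrix
(antiparallel flows summed): self-loops set to each node's maximum incident
weight, column normalization, then repeated expansion (matrix square) and
inflation (entrywise power, default 2.0) with pruning below 1e-5, up to 100
iterations or an elementwise change below 1e-8. Clusters are read off the
attractor rows; overlap is resolved by first-attractor assignment and any
orphaned gene becomes a singleton module. Non-convergence returns the
current hard clustering with a warning rather than failing.

## Meta-subnetworks

A meta-subnetwork over n associations weights each undirected gene link by
k/n, the fraction of association subnetworks containing it. The null model
draws, per replicate, each subnetwork's edge count uniformly without
replacement from the full interactome and integrates identically
(per-subnetwork resampling; a degree-preserving option weights edges by
endpoint-degree products, and a direct meta-edge-set resampler is also
provided). Observed vs pooled null weights are compared with a one-sided
unpaired Mann-Whitney U test — the unpaired test is the coherent choice for
two independent weight samples. All-equal pooled weights short-circuit to
p = 1 with a degeneracy flag.

## Evaluation

Because true mediators are largely unknown, labels are manufactured from
functional similarity: a subnetwork gene is a positive when its mean
similarity to the drug's known targets **and** to the disease's known genes
both exceed the 95th percentile of null distributions obtained by redrawing
reference sets of matched sizes from the annotated universe (default 1000
permutations, seeded). The null is pooled across the subnetwork's genes —
one distribution per reference side per association — which keeps the
percentile semantics while costing one pass per permutation. The pairwise
similarity is the Jaccard index of annotation term sets, mean-aggregated
over the reference set; it is an injectable function, since richer semantic
similarity measures (ontology-aware, best-match aggregated) are drop-in
replacements. AUROC is the tie-aware rank statistic; AUPRC is
step-integrated average precision. Enrichment is the hypergeometric upper
tail with Bonferroni correction across however many categories were tested.

## Synthetic study conditions

The generator emulates the *shape* of the real inputs, not their scale:
200 genes in 4 equally sized stochastic-block modules (intra-module edge
probability 0.25, weights 0.5–1.0; inter-module 0.01, weights 0.2–0.5), one
planted association per module with an ordered chain of 4 genes laid on
always-present maximum-weight edges. The chain's first gene is the drug's
known target, the last the disease's known gene, and the 2 interior genes
are the hidden truth; 2 decoy targets and 2 decoy disease genes per pair
(score 0.5 vs 1.0 for the true ones) make recovery non-trivial.
Annotations are module-coherent (6 terms per module, carried with
probability 0.9 inside, leaking at 0.05 outside). Weights are kept ≥ 0.2 so
costs stay finite; all randomness flows through one seeded generator, and a
fixed seed reproduces the bundle byte for byte.

What passing on these fixtures shows — and does not. The planted truth
makes recovery scoring exact, and the desk scale keeps every oracle
(vertex-enumeration LP, exhaustive path enumeration, pair-counting AUROC,
exact rank-sum permutation) affordable. It does not demonstrate
performance on genome-scale curated inputs: real interactomes have
heavy-tailed degree distributions, real drug–disease associations share
targets and genes across pairs, and real confidences are noisier than the
planted separation here. Problem sizes used throughout (200-gene default
fixtures, 10 replicate seeds for recovery, 100–200 random instances for
the oracle sweeps) were chosen as the smallest at which the qualitative
claims are statistically unambiguous.

## Numerical choices and edge cases

- LP feasibility/conservation tolerances: 1e-8 on node balance, 1e-9 slack
  on capacity bounds; objective agreement with independent solvers asserted
  at 1e-6.
- Genes referenced by drug/disease tables but absent from the interactome
  are dropped with a warning, and boundary normalization is computed over
  the retained genes, preserving the sum-to-1 invariants. A query with no
  mapped gene on either side is a model-construction error.
- The overlap ratio between target and disease gene sets uses the union
  denominator, keeping it in [0, 1].
- Permutation sampling for the gold standard is without replacement from
  the annotated universe; the seed is stored in the output object.
- Empty subnetworks (γ below every path cost) are valid outputs: ranking
  raises on them, the pipeline records them with a notice.

## Known limitations

- No similarity-based handling for drugs without any known target: such
  queries fail model construction by design.
- The uniform edge-sampling null for meta-subnetworks ignores degree
  structure unless the degree-preserving option is chosen.
- MCL module granularity depends on inflation; no model-selection over
  inflation is attempted.
- The LP is solved exactly; extremely large interactomes would need a
  specialized solver or decomposition, which is out of scope here.
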