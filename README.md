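# kddanet

Uncovering hidden genes that mediate known drug–disease associations by
minimum-cost network flow.

Curated resources record *that* a drug treats (or induces) a disease, but
rarely *how*: the cellular paths connecting the drug's protein targets to
the disease's genes run through intermediate genes that are neither known
targets nor known disease genes. `kddanet` infers those hidden mediators by
embedding a query drug and all of its associated diseases into a weighted
functional gene network, then asking which gene paths carry flow most
cheaply from drug to diseases.

## The model

For a query drug *S* (the **SDrTDi** context; a query disease is symmetric,
**SDiTDr**), a unified flow network is assembled:

- *S* → target gene *i* with weight `W_Si = P_i / Σ_{j∈T} P_j`
  (normalized drug–target confidence), capacity `C_Si = W_Si`;
- gene *i* ↔ gene *j* as antiparallel arcs weighted by the interactome's
  functional-linkage confidence rescaled into (0, 1], capacity 1 each way.
  Linkage confidences can be built from per-dataset evidence with
  log-likelihood scores `LLS = ln[(F(L|E)/~F(L|E)) / (F(L)/~F(L))]`
  combined across datasets with harmonic decay;
- disease-related gene *j* → disease *d* with the normalized disease–gene
  confidence `W_jd`, capacity `W_jd`;
- each disease *d* → sink *T* with weight `1/N` over the *N* diseases.

Every arc's cost is `−ln(weight)`, so cheap paths are high-probability
paths. The flow `F` solves the linear program

```
minimize   Σ_ij  −ln(W_ij)·F_ij  −  γ·Σ_v F_Sv
subject to flow conservation at every interior node,
           source out-flow = sink in-flow,
           0 ≤ F_ij ≤ C_ij
```

where γ rewards each unit of flow pushed through the network: a path
carries flow exactly when γ exceeds its summed cost, so γ trades subnetwork
size against confidence (defaults: γ = 6 for SDrTDi, γ = 8 for SDiTDr).
The positive-flow subgraph is decomposed per association (all directed
source→endpoint paths), genes are ranked by the flow they carry, and each
association subnetwork is partitioned into modules with the Markov Cluster
algorithm using flow amounts as edge weights. Meta-subnetworks integrate
many associations sharing a drug or disease, weighting each gene link by
the fraction of subnetworks containing it, tested against matched-size
random subnetworks with a rank-sum test.

## Worked example

All inputs are plain TSV; the `simulate` subcommand writes a synthetic
bundle with planted mediating chains so the pipeline can be exercised
without any downloads:

```
$ kddanet simulate --n-genes 200 --n-modules 4 --chain-length 4 --seed 1 --out demo/inputs
1344 edges, 4 planted associations -> demo/inputs

$ kddanet run --network demo/inputs/gene_network.tsv \
              --drug-targets demo/inputs/drug_targets.tsv \
              --disease-genes demo/inputs/disease_genes.tsv \
              --kdda demo/inputs/kdda.tsv \
              --query DRUG0 --gamma 6 --out demo/run
query DRUG0: total flow 1.0000, 1 association subnetwork(s) -> demo/run

$ head -6 demo/run/DRUG0__DIS0.ranked_genes.tsv
gene    flow_through    rank
G0000   0.5     1
G0001   0.5     2
G0002   0.5     3
G0003   0.5     4
G0015   0.25    5
```

`DRUG0`'s planted chain is `G0000 → G0001 → G0002 → G0003`: the first gene
is the known target, the last the known disease gene, and the two interior
genes are the hidden mediators. The run recovers the whole chain at the top
of the flow ranking — each chain gene carries 0.5 units of flow (the
capacity of the source→target arc), while decoy-target paths carry at most
0.25. The total flow of 1.0 means every source arc saturated, i.e. γ = 6
exceeded the cost of the cheapest path from every target. Per-association
module labels (`*.modules.tsv`), the subnetwork arcs (`*.subnetwork.tsv`,
`.sif` for Cytoscape-style viewers) and a reproducibility manifest are
written alongside.

Other subcommands: `build` (export the flow network without solving),
`solve`, `decompose`, `meta` (shared-link meta-subnetwork plus random-null
rank-sum test) and `evaluate` (permutation gold standard and AUROC/AUPRC
for one association).

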