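"""Reproducible synthetic inputs with planted mediating pathways.

Real inputs to this kind of analysis are genome-scale curated resources
(an integrated functional interactome, drug-target and disease-gene tables);
this module generates desk-scale stand-ins with known ground truth so every
pipeline stage can be exercised and scored without downloads.

The interactome is a stochastic-block-style graph: dense modules with
high-confidence edges, sparse low-confidence bridges. Each planted
association gets an ordered gene chain inside one module: the chain's first
gene is the drug's target, the last is the disease's related gene, and the
interior genes are the hidden mediators the flow optimization should
recover. Decoy targets and disease genes are added so recovery is not
trivial, and module-coherent annotation terms (with leak noise) support the
functional-similarity evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import AnnotationTable
from .model import (
    DiseaseGeneTable,
    DrugTargetTable,
    GeneNetwork,
    KddaTable,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults: 200 genes in 4 modules, one planted association per module
    with a chain of length 4 (two hidden mediators each). Intra-module
    edges are common and high-confidence (p 0.25, weights 0.5–1.0);
    inter-module edges rare and weak (p 0.01, weights 0.2–0.5). Weights stay
    >= 0.2 so negative-log costs stay finite and bounded.
    """

    n_genes: int = 200
    n_modules: int = 4
    p_intra: float = 0.25
    intra_weight_range: tuple[float, float] = (0.5, 1.0)
    p_inter: float = 0.01
    inter_weight_range: tuple[float, float] = (0.2, 0.5)
    chain_length: int = 4
    chains_per_module: int = 1
    n_decoy_targets: int = 2
    n_decoy_disease_genes: int = 2
    decoy_score: float = 0.5
    true_score: float = 1.0
    terms_per_module: int = 6
    p_term_within: float = 0.9
    p_term_leak: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_intra, self.p_inter, self.p_term_within,
                  self.p_term_leak):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.chain_length < 2:
            raise ValueError("a planted chain needs at least 2 genes")
        if self.chain_length > self.module_size:
            raise ValueError("planted chain longer than a module")
        if self.n_genes % self.n_modules != 0:
            raise ValueError("n_genes must split evenly into modules")

    @property
    def module_size(self) -> int:
        return self.n_genes // self.n_modules

    def gene_name(self, i: int) -> str:
        return f"G{i:04d}"

    def module_of(self, i: int) -> int:
        return i // self.module_size

    def planted_paths(self) -> list[tuple[str, str, tuple[str, ...]]]:
        """(drug, disease, ordered gene chain) per planted association.

        Chains occupy the leading genes of each module, laid out
        deterministically so truth is a pure function of the spec.
        """
        out = []
        k = 0
        for m in range(self.n_modules):
            base = m * self.module_size
            for c in range(self.chains_per_module):
                start = base + c * self.chain_length
                if start + self.chain_length > base + self.module_size:
                    raise ValueError("module too small for requested chains")
                chain = tuple(
                    self.gene_name(start + j) for j in range(self.chain_length)
                )
                out.append((f"DRUG{k}", f"DIS{k}", chain))
                k += 1
        return out


@dataclass
class FixtureData:
    """All generated tables for one spec, plus the planted truth."""

    spec: FixtureSpec
    gene_network: GeneNetwork
    drug_targets: DrugTargetTable
    disease_genes: DiseaseGeneTable
    kddas: KddaTable
    annotations: AnnotationTable
    truth: dict[tuple[str, str], set[str]] = field(default_factory=dict)


def generate_interactome(spec: FixtureSpec) -> GeneNetwork:
    """Stochastic-block interactome with planted chains always connected.

    Every non-planted gene pair is an independent Bernoulli draw
    (``p_intra`` within a module, ``p_inter`` across); consecutive planted
    chain genes are connected with the maximum intra-module weight.
    """
    rng = np.random.default_rng(spec.seed)
    gn = GeneNetwork()
    gn.nodes.update(spec.gene_name(i) for i in range(spec.n_genes))

    planted: set[tuple[str, str]] = set()
    for _, _, chain in spec.planted_paths():
        for a, b in zip(chain, chain[1:]):
            planted.add((a, b) if a <= b else (b, a))

    lo_in, hi_in = spec.intra_weight_range
    lo_out, hi_out = spec.inter_weight_range
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            a, b = spec.gene_name(i), spec.gene_name(j)
            key = (a, b) if a <= b else (b, a)
            same = spec.module_of(i) == spec.module_of(j)
            if key in planted:
                continue
            p = spec.p_intra if same else spec.p_inter
            if rng.random() < p:
                lo, hi = (lo_in, hi_in) if same else (lo_out, hi_out)
                gn.edges[key] = float(rng.uniform(lo, hi))
    for key in sorted(planted):
        gn.edges[key] = hi_in
    return gn


def generate_entities(
    spec: FixtureSpec, gn: GeneNetwork
) -> tuple[DrugTargetTable, DiseaseGeneTable, KddaTable, AnnotationTable]:
    """Drug-target / disease-gene / association / annotation tables.

    Per planted pair: the chain's first gene is the true target, the last
    the true disease gene (both at ``true_score``); decoys are drawn from
    genes outside the pair's own chain at ``decoy_score``. Annotation terms
    are module-coherent with leak noise.
    """
    rng = np.random.default_rng(spec.seed + 1)
    dt = DrugTargetTable()
    dg = DiseaseGeneTable()
    kddas = KddaTable()
    all_genes = [spec.gene_name(i) for i in range(spec.n_genes)]

    for drug, disease, chain in spec.planted_paths():
        dt.add(drug, chain[0], spec.true_score)
        dg.add(disease, chain[-1], spec.true_score)
        pool = [g for g in all_genes if g not in chain]
        n_decoy = spec.n_decoy_targets + spec.n_decoy_disease_genes
        picks = rng.choice(len(pool), size=n_decoy, replace=False)
        for p in picks[: spec.n_decoy_targets]:
            dt.add(drug, pool[p], spec.decoy_score)
        for p in picks[spec.n_decoy_targets:]:
            dg.add(disease, pool[p], spec.decoy_score)
        kddas.add(drug, disease, disease_type="synthetic")

    ann = AnnotationTable()
    for i, g in enumerate(all_genes):
        home = spec.module_of(i)
        for m in range(spec.n_modules):
            p = spec.p_term_within if m == home else spec.p_term_leak
            for t in range(spec.terms_per_module):
                if rng.random() < p:
                    ann.add(g, f"TERM_M{m}_{t}")
    return dt, dg, kddas, ann


def truth_table(spec: FixtureSpec) -> dict[tuple[str, str], set[str]]:
    """Planted interior (hidden) genes per association."""
    return {
        (drug, disease): set(chain[1:-1])
        for drug, disease, chain in spec.planted_paths()
    }


def generate(spec: FixtureSpec) -> FixtureData:
    """Generate the full fixture bundle for one spec."""
    gn = generate_interactome(spec)
    dt, dg, kddas, ann = generate_entities(spec, gn)
    return FixtureData(
        spec=spec, gene_network=gn, drug_targets=dt, disease_genes=dg,
        kddas=kddas, annotations=ann, truth=truth_table(spec),
    )


def hidden_gene_recovery(
    spec: FixtureSpec, gamma: float = 6.0, context: str = "SDrTDi"
) -> dict[tuple[str, str], float]:
    """End-to-end recovery score: per planted association, the AUROC of
    flow-through-ranked genes against the planted hidden mediators.

    Candidates are all interactome genes except the pair's own known targets
    and disease genes; a gene absent from the association's subnetwork
    scores 0 flow.
    """
    from sklearn.metrics import roc_auc_score

    from .decompose import extract_kdda_subnetwork, rank_genes_by_flow
    from .flow import solve_network
    from .model import build_flow_network

    data = generate(spec)
    out: dict[tuple[str, str], float] = {}
    queries = sorted({p[0] for p in data.kddas.pairs}) if context == "SDrTDi" \
        else sorted({p[1] for p in data.kddas.pairs})
    for query in queries:
        net = build_flow_network(
            query, context, data.gene_network, data.drug_targets,
            data.disease_genes, data.kddas,
        )
        flowsub = solve_network(net, gamma=gamma)
        endpoints = data.kddas.diseases_of(query) if context == "SDrTDi" \
            else data.kddas.drugs_of(query)
        for ep in endpoints:
            pair = (query, ep) if context == "SDrTDi" else (ep, query)
            drug, disease = pair
            hidden = data.truth[pair]
            known = set(data.drug_targets.targets(drug)) | set(
                data.disease_genes.genes(disease))
            sub = extract_kdda_subnetwork(flowsub, ep)
            scores = dict.fromkeys(
                (g for g in data.gene_network.nodes if g not in known), 0.0)
            if sub.arcs:
                for g, f in rank_genes_by_flow(sub):
                    if g in scores:
                        scores[g] = f
            genes = sorted(scores)
            y = [1 if g in hidden else 0 for g in genes]
            s = [scores[g] for g in genes]
            out[pair] = float(roc_auc_score(y, s))
    return out
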