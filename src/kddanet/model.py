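"""Domain types and construction of the unified drug–gene–disease flow network.

The central object is the :class:`FlowNetwork`: a directed graph with one
source (the query drug or disease), a layer of gene nodes carrying the
weighted interactome, a layer of endpoint nodes (the diseases associated with
a query drug, or the drugs associated with a query disease), and one sink.
Every arc carries a probability-like weight in (0, 1], a capacity, and a cost
equal to the negative log of its weight, so that minimum-cost flow prefers
the highest-probability drug→gene→…→gene→endpoint paths.

Two query contexts are supported:

``SDrTDi``
    single drug to diseases — the drug is the flow source; each associated
    disease feeds the sink.
``SDiTDr``
    single disease to drugs — the disease is the source; each associated drug
    feeds the sink.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

SDRTDI = "SDrTDi"
SDITDR = "SDiTDr"

SOURCE = "__SOURCE__"
SINK = "__SINK__"


class ModelError(ValueError):
    """Raised when a flow model cannot be constructed from the inputs."""


# ---------------------------------------------------------------------------
# evidence integration (log-likelihood scores)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceLinkageCounts:
    """Linkage counts of one evidence dataset against annotated pathways.

    ``f_l_given_e`` / ``notf_l_given_e`` count gene linkages observed in the
    dataset that fall within / between annotated pathways; ``f_l`` /
    ``notf_l`` are the same counts over all annotated gene pairs,
    unconditioned on the dataset.
    """

    f_l_given_e: int
    notf_l_given_e: int
    f_l: int
    notf_l: int

    def __post_init__(self) -> None:
        for name in ("f_l_given_e", "notf_l_given_e", "f_l", "notf_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")


def compute_lls(counts: EvidenceLinkageCounts) -> float:
    """Log-likelihood score of a linkage under one evidence dataset.

    ``ln[(F(L|E)/~F(L|E)) / (F(L)/~F(L))]`` — positive when the dataset's
    linkages are enriched within annotated pathways relative to the prior.
    """
    for name in ("f_l_given_e", "notf_l_given_e", "f_l", "notf_l"):
        if getattr(counts, name) == 0:
            raise ValueError(
                f"LLS undefined: count {name} is zero (ratio degenerate)"
            )
    cond = counts.f_l_given_e / counts.notf_l_given_e
    prior = counts.f_l / counts.notf_l
    return math.log(cond / prior)


def combine_lls(scores: Iterable[float], d: float = 2.0, t: float = 1.0) -> float:
    """Combine per-dataset log-likelihood scores into one linkage weight.

    Scores below the threshold ``t`` are discarded; the rest are sorted in
    descending order and combined as ``best + sum_i rest_i / (d * i)`` with
    ``i = 1`` at the second-best score, so additional evidence contributes
    with harmonic decay controlled by ``d``.
    """
    if d <= 0:
        raise ValueError("decay rate d must be positive")
    kept = sorted((s for s in scores if s >= t), reverse=True)
    if not kept:
        raise ValueError(
            f"no evidence: all LLS scores fell below threshold T={t}"
        )
    best, rest = kept[0], kept[1:]
    return best + sum(s / (d * i) for i, s in enumerate(rest, start=1))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


@dataclass
class GeneNetwork:
    """Undirected weighted functional gene network.

    Edges are stored once under a sorted gene-pair key; weights are positive
    functional-linkage confidences (unitless, unbounded above).
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on gene {a!r} not allowed")
        if weight <= 0:
            raise ValueError(f"edge ({a},{b}) weight must be > 0, got {weight}")
        key = self._key(a, b)
        if key in self.edges and not math.isclose(self.edges[key], weight):
            raise ValueError(
                f"conflicting duplicate edge {key}: "
                f"{self.edges[key]} vs {weight}"
            )
        self.edges[key] = weight
        self.nodes.update(key)

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.edges

    def weight(self, a: str, b: str) -> float:
        return self.edges[self._key(a, b)]

    def neighbors(self, g: str) -> set[str]:
        out: set[str] = set()
        for (a, b) in self.edges:
            if a == g:
                out.add(b)
            elif b == g:
                out.add(a)
        return out

    def __len__(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "GeneNetwork":
        gn = cls()
        for a, b, w in records:
            gn.add_edge(a, b, float(w))
        return gn


@dataclass
class DrugTargetTable:
    """drug → {target gene → positive confidence score}."""

    scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, drug: str, gene: str, score: float) -> None:
        if score <= 0:
            raise ValueError(
                f"drug-target score for ({drug},{gene}) must be > 0"
            )
        self.scores.setdefault(drug, {})[gene] = score

    def targets(self, drug: str) -> dict[str, float]:
        if drug not in self.scores:
            raise KeyError(f"unknown drug {drug!r}")
        return self.scores[drug]

    def drugs(self) -> set[str]:
        return set(self.scores)


@dataclass
class DiseaseGeneTable:
    """disease → {related gene → positive confidence score}."""

    scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, disease: str, gene: str, score: float) -> None:
        if score <= 0:
            raise ValueError(
                f"disease-gene score for ({disease},{gene}) must be > 0"
            )
        self.scores.setdefault(disease, {})[gene] = score

    def genes(self, disease: str) -> dict[str, float]:
        if disease not in self.scores:
            raise KeyError(f"unknown disease {disease!r}")
        return self.scores[disease]

    def diseases(self) -> set[str]:
        return set(self.scores)


@dataclass
class KddaTable:
    """Curated known drug-disease associations, with optional disease types."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    disease_types: dict[str, str] = field(default_factory=dict)

    def add(self, drug: str, disease: str, disease_type: str | None = None) -> None:
        pair = (drug, disease)
        if pair in self.pairs:
            raise ValueError(f"duplicate KDDA pair {pair}")
        self.pairs.append(pair)
        if disease_type is not None:
            self.disease_types[disease] = disease_type

    def diseases_of(self, drug: str) -> list[str]:
        return [d for (dr, d) in self.pairs if dr == drug]

    def drugs_of(self, disease: str) -> list[str]:
        return [dr for (dr, d) in self.pairs if d == disease]


# ---------------------------------------------------------------------------
# normalized boundary weights
# ---------------------------------------------------------------------------


def _normalize(scores: Mapping[str, float]) -> dict[str, float]:
    total = sum(scores.values())
    return {g: s / total for g, s in scores.items()}


def normalize_drug_target_weights(
    drug: str, table: DrugTargetTable
) -> dict[str, float]:
    """Normalized source→target weights: W_Si = P_i / sum_j P_j over targets."""
    return _normalize(table.targets(drug))


def normalize_disease_gene_weights(
    disease: str, table: DiseaseGeneTable
) -> dict[str, float]:
    """Normalized gene→disease weights: F_i / sum over the disease's genes."""
    return _normalize(table.genes(disease))


# ---------------------------------------------------------------------------
# flow network
# ---------------------------------------------------------------------------


@dataclass
class Arc:
    weight: float  # probability-like, in (0, 1]
    capacity: float
    cost: float  # -ln(weight)


@dataclass
class FlowNetwork:
    """Directed arc-weighted graph with a single source and sink.

    ``node_kind`` maps each node id to one of ``source | gene | endpoint |
    sink``; endpoints are the diseases (SDrTDi) or drugs (SDiTDr) feeding the
    sink. ``arcs`` maps ``(u, v)`` to an :class:`Arc`.
    """

    context: str
    source: str
    sink: str
    node_kind: dict[str, str] = field(default_factory=dict)
    arcs: dict[tuple[str, str], Arc] = field(default_factory=dict)

    def add_arc(self, u: str, v: str, weight: float, capacity: float) -> None:
        if not (0.0 < weight <= 1.0 + 1e-12):
            raise ValueError(f"arc ({u},{v}) weight {weight} outside (0, 1]")
        if capacity <= 0:
            raise ValueError(f"arc ({u},{v}) capacity must be positive")
        self.arcs[(u, v)] = Arc(weight=weight, capacity=capacity,
                                cost=-math.log(min(weight, 1.0)))

    @property
    def genes(self) -> set[str]:
        return {n for n, k in self.node_kind.items() if k == "gene"}

    @property
    def endpoints(self) -> set[str]:
        return {n for n, k in self.node_kind.items() if k == "endpoint"}

    def source_arcs(self) -> list[tuple[str, str]]:
        return [a for a in self.arcs if a[0] == self.source]

    def out_arcs(self, u: str) -> list[tuple[str, str]]:
        return [a for a in self.arcs if a[0] == u]

    def in_arcs(self, v: str) -> list[tuple[str, str]]:
        return [a for a in self.arcs if a[1] == v]


def build_flow_network(
    query: str,
    context: str,
    gn: GeneNetwork,
    dt: DrugTargetTable,
    dg: DiseaseGeneTable,
    kddas: KddaTable,
) -> FlowNetwork:
    """Assemble the unified flow network for one query drug or disease.

    In the SDrTDi context the query drug becomes the source with arcs to its
    target genes (normalized target scores as weights and capacities), the
    interactome contributes antiparallel gene–gene arc pairs (weights are
    linkage confidences rescaled by the global maximum into (0, 1], capacity
    1 each way), each associated disease receives arcs from its related genes
    (normalized disease-gene scores, capacity = weight) and sends one arc of
    weight 1/N to the sink. The SDiTDr context mirrors this with the disease
    as source and its drugs as endpoints. Genes absent from the interactome
    are dropped with a warning; every arc's cost is ``-ln(weight)``.
    """
    if context not in (SDRTDI, SDITDR):
        raise ValueError(f"unknown context {context!r}")

    if context == SDRTDI:
        source_gene_scores = dt.targets(query)  # raises on unknown drug
        endpoint_ids = kddas.diseases_of(query)
        endpoint_gene_scores = {d: dg.genes(d) for d in endpoint_ids}
    else:
        source_gene_scores = dg.genes(query)
        endpoint_ids = kddas.drugs_of(query)
        endpoint_gene_scores = {d: dt.targets(d) for d in endpoint_ids}

    # restrict to genes present in the interactome, warn on drops
    src_kept = {g: s for g, s in source_gene_scores.items() if g in gn.nodes}
    dropped = set(source_gene_scores) - set(src_kept)
    if dropped:
        log.warning(
            "query %s: %d source-side gene(s) absent from gene network, "
            "dropped: %s", query, len(dropped), sorted(dropped))
    if not src_kept:
        raise ModelError(
            f"query {query!r} has no mapped source-side genes in the gene "
            "network; cannot construct a flow model")

    ep_kept: dict[str, dict[str, float]] = {}
    for ep, scores in endpoint_gene_scores.items():
        kept = {g: s for g, s in scores.items() if g in gn.nodes}
        missing = set(scores) - set(kept)
        if missing:
            log.warning(
                "endpoint %s: %d gene(s) absent from gene network, dropped: %s",
                ep, len(missing), sorted(missing))
        if kept:
            ep_kept[ep] = kept
        else:
            log.warning("endpoint %s has no mapped genes; dropped", ep)
    if not ep_kept:
        raise ModelError(
            f"query {query!r} has no associated endpoint with mapped genes; "
            "cannot construct a flow model")

    net = FlowNetwork(context=context, source=SOURCE, sink=SINK)
    net.node_kind[SOURCE] = "source"
    net.node_kind[SINK] = "sink"
    for g in gn.nodes:
        net.node_kind[g] = "gene"
    for ep in ep_kept:
        net.node_kind[ep] = "endpoint"

    # source → gene arcs, normalized over retained genes
    for g, w in _normalize(src_kept).items():
        net.add_arc(SOURCE, g, weight=w, capacity=w)

    # gene ↔ gene antiparallel arcs, weights rescaled by the global max
    if gn.edges:
        wmax = max(gn.edges.values())
        for (a, b), w in gn.edges.items():
            p = w / wmax
            net.add_arc(a, b, weight=p, capacity=1.0)
            net.add_arc(b, a, weight=p, capacity=1.0)

    # gene → endpoint arcs, normalized per endpoint; endpoint → sink = 1/N
    n_ep = len(ep_kept)
    for ep, scores in ep_kept.items():
        for g, w in _normalize(scores).items():
            net.add_arc(g, ep, weight=w, capacity=w)
        net.add_arc(ep, SINK, weight=1.0 / n_ep, capacity=1.0 / n_ep)

    return net
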