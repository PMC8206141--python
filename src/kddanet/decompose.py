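"""Decompose the optimal flow subnetwork into per-association pieces.

One minimum-cost-flow solve covers a query and all its associated endpoints
at once; the subnetwork mediating a single drug-disease association is then
the union of all directed source→endpoint paths inside the positive-flow
graph. Genes on that subnetwork are ranked by the flow they carry, and the
gene–gene part is partitioned into modules with the Markov Cluster algorithm
(MCL), using flow amounts as edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .flow import FlowSubnetwork

log = logging.getLogger(__name__)


@dataclass
class KddaSubnetwork:
    """All source→endpoint paths for one association, with flow amounts."""

    query: str
    endpoint: str
    arcs: dict[tuple[str, str], float]
    network: "object" = field(repr=False, default=None)  # parent FlowNetwork

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for u, v in self.arcs:
            out.update((u, v))
        return out

    @property
    def genes(self) -> set[str]:
        if self.network is None:
            return {n for n in self.nodes
                    if n not in (self.endpoint, self.query)}
        return {n for n in self.nodes
                if self.network.node_kind.get(n) == "gene"}

    def gene_edges(self) -> dict[tuple[str, str], float]:
        """Undirected gene–gene edges with antiparallel flows summed."""
        genes = self.genes
        out: dict[tuple[str, str], float] = {}
        for (u, v), f in self.arcs.items():
            if u in genes and v in genes:
                key = (u, v) if u <= v else (v, u)
                out[key] = out.get(key, 0.0) + f
        return out

    def __len__(self) -> int:
        return len(self.arcs)


def extract_kdda_subnetwork(
    flowsub: FlowSubnetwork, endpoint: str
) -> KddaSubnetwork:
    """Arcs lying on some directed source→endpoint path of the flow graph.

    An arc (u, v) is kept iff u is reachable from the source and the endpoint
    is reachable from v. Private branches feeding other endpoints, and the
    endpoint→sink arcs, are excluded.
    """
    net = flowsub.network
    g = nx.DiGraph()
    g.add_nodes_from(flowsub.nodes)
    for (u, v), f in flowsub.arcs.items():
        g.add_edge(u, v, flow=f)

    if endpoint not in g or net.source not in g:
        log.info("endpoint %s carried no flow; empty subnetwork", endpoint)
        return KddaSubnetwork(query=net.source, endpoint=endpoint, arcs={},
                              network=net)

    from_source = nx.descendants(g, net.source) | {net.source}
    to_endpoint = nx.ancestors(g, endpoint) | {endpoint}
    arcs = {
        (u, v): f
        for (u, v), f in flowsub.arcs.items()
        if u in from_source and v in to_endpoint
    }
    if not arcs:
        log.info("endpoint %s carried no flow; empty subnetwork", endpoint)
    return KddaSubnetwork(query=net.source, endpoint=endpoint, arcs=arcs,
                          network=net)


def rank_genes_by_flow(sub: KddaSubnetwork) -> list[tuple[str, float]]:
    """Genes ordered by flow-through (total inbound flow), descending.

    Ties break lexicographically on the gene id. By conservation a gene's
    inbound flow in the full solution equals its outbound flow; within one
    association's subnetwork inbound is the natural reading of "flow carried".
    """
    if not sub.arcs:
        raise ValueError("cannot rank genes of an empty subnetwork")
    through: dict[str, float] = {g: 0.0 for g in sub.genes}
    for (u, v), f in sub.arcs.items():
        if v in through:
            through[v] += f
    return sorted(through.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_threshold < 0:
            raise ValueError("prune threshold must be non-negative")
        if self.max_iterations < 1 or self.tolerance <= 0:
            raise ValueError("max_iterations >= 1 and tolerance > 0 required")


def mcl_matrix(
    matrix: np.ndarray, params: MclParams
) -> tuple[list[list[int]], bool]:
    """Run MCL on a symmetric non-negative adjacency matrix.

    Returns (clusters as lists of column indices, converged flag). Self-loops
    are set to each node's maximum incident weight before normalization.
    Clusters are read from the attractors (rows with positive diagonal) of
    the limit matrix; every column is assigned to exactly one cluster.
    """
    m = np.asarray(matrix, dtype=float).copy()
    n = m.shape[0]
    if n == 0:
        return [], True
    loop = m.max(axis=1)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(m, loop)
    m = m / m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(params.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)  # expansion
        m = np.power(m, params.inflation)  # inflation
        m[m < params.prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < params.tolerance:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge in %d iterations; returning the "
                    "current hard clustering", params.max_iterations)

    attractors = np.where(np.diag(m) > 1e-9)[0]
    assigned = np.full(n, -1, dtype=int)
    clusters: list[list[int]] = []
    for a in attractors:
        members = np.where(m[a] > 1e-9)[0]
        members = [j for j in members if assigned[j] == -1]
        if not members:
            continue
        cid = len(clusters)
        for j in members:
            assigned[j] = cid
        clusters.append(list(members))
    for j in np.where(assigned == -1)[0]:  # orphans become singletons
        assigned[j] = len(clusters)
        clusters.append([int(j)])
    return clusters, converged


def mcl_cluster(
    sub: KddaSubnetwork, params: MclParams | None = None
) -> dict[str, int]:
    """Partition the subnetwork's genes into modules by MCL.

    Gene–gene arcs are symmetrized (antiparallel flows summed) into a
    weighted adjacency; drug, disease and sink nodes are excluded. Singleton
    attractors are kept as size-1 modules. The labeling is deterministic for
    a fixed input.
    """
    params = params or MclParams()
    genes = sorted(sub.genes)
    if not genes:
        return {}
    idx = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)))
    for (a, b), f in sub.gene_edges().items():
        adj[idx[a], idx[b]] = f
        adj[idx[b], idx[a]] = f
    clusters, _ = mcl_matrix(adj, params)
    # stable module ids: order clusters by their smallest gene id
    clusters = sorted(clusters, key=lambda c: min(genes[j] for j in c))
    labels: dict[str, int] = {}
    for cid, members in enumerate(clusters):
        for j in members:
            labels[genes[j]] = cid
    return labels
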