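"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the LP
oracle enumerates basic feasible solutions (polytope vertices) directly, the
path oracle enumerates all simple source→endpoint paths, and AUROC is
counted over positive/negative pairs.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from kddanet.model import (
    DiseaseGeneTable,
    DrugTargetTable,
    FlowNetwork,
    GeneNetwork,
    KddaTable,
    build_flow_network,
)


# ---------------------------------------------------------------------------
# tiny deterministic model inputs
# ---------------------------------------------------------------------------


@pytest.fixture
def tiny_tables():
    """Drug D1 → {g1, g2}; diseases s1 (genes g3, g4), s2 (gene g4);
    6-gene interactome."""
    gn = GeneNetwork.from_records([
        ("g1", "g2", 1.0),
        ("g1", "g3", 0.8),
        ("g2", "g4", 0.6),
        ("g3", "g4", 0.9),
        ("g2", "g5", 0.5),
        ("g5", "g6", 0.4),
    ])
    dt = DrugTargetTable()
    dt.add("D1", "g1", 2.0)
    dt.add("D1", "g2", 2.0)
    dg = DiseaseGeneTable()
    dg.add("s1", "g3", 1.0)
    dg.add("s1", "g4", 3.0)
    dg.add("s2", "g4", 5.0)
    kd = KddaTable()
    kd.add("D1", "s1")
    kd.add("D1", "s2")
    return gn, dt, dg, kd


@pytest.fixture
def tiny_network(tiny_tables) -> FlowNetwork:
    gn, dt, dg, kd = tiny_tables
    return build_flow_network("D1", "SDrTDi", gn, dt, dg, kd)


def single_path_network(weights: list[float]) -> FlowNetwork:
    """S → g1 → … → gk → d → T with the given per-arc weights (k = len-3)."""
    assert len(weights) >= 3
    net = FlowNetwork(context="SDrTDi", source="S", sink="T")
    nodes = (["S"] + [f"g{i}" for i in range(1, len(weights) - 1)]
             + ["d", "T"])
    net.node_kind["S"] = "source"
    net.node_kind["T"] = "sink"
    net.node_kind["d"] = "endpoint"
    for n in nodes[1:-2]:
        net.node_kind[n] = "gene"
    for (u, v), w in zip(zip(nodes, nodes[1:]), weights):
        net.add_arc(u, v, weight=w, capacity=1.0 if u != "S" else w)
    return net


def random_model_network(rng: np.random.Generator,
                         n_genes: int = 4,
                         n_diseases: int = 2) -> FlowNetwork:
    """A small random but valid flow network built through the model layer.

    Node count = n_genes + n_diseases + 2 (source, sink) <= 10 for the
    defaults; weights generic (continuous) so optima are almost surely
    unique.
    """
    genes = [f"g{i}" for i in range(n_genes)]
    gn = GeneNetwork()
    gn.nodes.update(genes)
    for a, b in itertools.combinations(genes, 2):
        if rng.random() < 0.6:
            gn.add_edge(a, b, float(rng.uniform(0.2, 1.0)))
    dt = DrugTargetTable()
    for g in rng.choice(genes, size=rng.integers(1, 3), replace=False):
        dt.add("D", str(g), float(rng.uniform(0.5, 2.0)))
    dg = DiseaseGeneTable()
    kd = KddaTable()
    for d in range(n_diseases):
        dis = f"s{d}"
        for g in rng.choice(genes, size=rng.integers(1, 3), replace=False):
            dg.add(dis, str(g), float(rng.uniform(0.5, 2.0)))
        kd.add("D", dis)
    return build_flow_network("D", "SDrTDi", gn, dt, dg, kd)


# ---------------------------------------------------------------------------
# LP oracle: exhaustive vertex (basic feasible solution) enumeration
# ---------------------------------------------------------------------------


def brute_force_lp(c, a_eq, bounds) -> float:
    """Minimum of c·x over {A x = 0, l <= x <= u} by enumerating all basic
    feasible solutions; independent of any iterative LP solver."""
    a = np.asarray(a_eq.todense()) if hasattr(a_eq, "todense") \
        else np.asarray(a_eq, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(c)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    r = np.linalg.matrix_rank(a)
    best = math.inf
    for basic in itertools.combinations(range(n), r):
        ab = a[:, basic]
        if np.linalg.matrix_rank(ab) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for bits in itertools.product((0, 1), repeat=len(nonbasic)):
            xn = np.where(bits, hi[nonbasic], lo[nonbasic])
            rhs = -a[:, nonbasic] @ xn if nonbasic else np.zeros(a.shape[0])
            xb, *_ = np.linalg.lstsq(ab, rhs, rcond=None)
            if np.linalg.norm(ab @ xb - rhs) > 1e-8:
                continue
            x = np.empty(n)
            x[list(basic)] = xb
            x[nonbasic] = xn
            if np.all(x >= lo - 1e-9) and np.all(x <= hi + 1e-9):
                best = min(best, float(c @ x))
    return best


# ---------------------------------------------------------------------------
# path oracle and random flow DAGs
# ---------------------------------------------------------------------------


def enumerate_path_arcs(arcs: dict, source: str, endpoint: str) -> set:
    """All arcs on any simple source→endpoint path, by exhaustive
    enumeration with networkx."""
    g = nx.DiGraph(list(arcs))
    if source not in g or endpoint not in g:
        return set()
    out: set = set()
    for path in nx.all_simple_paths(g, source, endpoint):
        out.update(zip(path, path[1:]))
    return out


def random_flow_dag(rng: np.random.Generator, n_nodes: int = 10,
                    n_endpoints: int = 2, n_paths: int = 5):
    """A random positive-flow subnetwork built as a union of random
    source→endpoint→sink paths (so flow conservation holds and every arc
    lies on some path). Returns a FlowSubnetwork-compatible object."""
    from kddanet.flow import FlowSubnetwork

    n_genes = n_nodes - 2 - n_endpoints
    genes = [f"g{i}" for i in range(n_genes)]
    endpoints = [f"d{i}" for i in range(n_endpoints)]
    net = FlowNetwork(context="SDrTDi", source="S", sink="T")
    net.node_kind.update({"S": "source", "T": "sink"})
    net.node_kind.update({g: "gene" for g in genes})
    net.node_kind.update({d: "endpoint" for d in endpoints})

    arcs: dict = {}
    for _ in range(n_paths):
        k = int(rng.integers(1, max(2, n_genes + 1)))
        # ascending gene indices keep the graph acyclic
        idx = sorted(rng.choice(n_genes, size=k, replace=False))
        ep = endpoints[int(rng.integers(n_endpoints))]
        path = ["S"] + [genes[i] for i in idx] + [ep, "T"]
        f = float(rng.uniform(0.1, 1.0))
        for u, v in zip(path, path[1:]):
            arcs[(u, v)] = arcs.get((u, v), 0.0) + f
    return FlowSubnetwork(arcs=arcs, network=net)


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------


def auroc_by_pair_counting(scores: dict, positives: set) -> float:
    """Probability a random positive outranks a random negative, ties 1/2."""
    pos = [s for g, s in scores.items() if g in positives]
    neg = [s for g, s in scores.items() if g not in positives]
    assert pos and neg
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def exact_ranksum_p_greater(x: list, y: list) -> float:
    """Exact permutation p-value for the Mann-Whitney U statistic,
    one-sided (x greater), by enumerating all group assignments."""
    def u_stat(a, b):
        return sum(1.0 if i > j else 0.5 if i == j else 0.0
                   for i in a for j in b)

    observed = u_stat(x, y)
    pooled = list(x) + list(y)
    n = len(x)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if u_stat(a, b) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total
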