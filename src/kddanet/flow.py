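"""Minimum-cost-flow linear program over the unified flow network.

The objective trades total arc cost against a reward ``gamma`` per unit of
flow leaving the source::

    minimize  sum_ij cost_ij * F_ij  -  gamma * sum_v F_Sv
    s.t.      flow conservation at every interior node
              total source out-flow == total sink in-flow
              0 <= F_ij <= C_ij

Because costs are non-negative and the zero flow is always feasible, gamma
acts as a per-unit budget: a source→sink path carries flow only when gamma
exceeds its summed arc cost, so larger gamma admits larger but
lower-confidence subnetworks. The reward term makes this a generic LP rather
than a classical min-cost-flow instance; it is solved exactly with the HiGHS
simplex implementation behind :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .model import FlowNetwork

DEFAULT_GAMMA = {"SDrTDi": 6.0, "SDiTDr": 8.0}
DEFAULT_EPSILON = 1e-8


class SolverError(RuntimeError):
    """LP solver failed to return an optimal solution."""


@dataclass
class FlowProblem:
    """LP formulation: one bounded variable per arc, equality constraints."""

    network: FlowNetwork
    gamma: float
    arc_index: list[tuple[str, str]]  # variable order
    costs: np.ndarray  # objective coefficients (cost, minus gamma on source arcs)
    a_eq: csr_matrix
    b_eq: np.ndarray
    bounds: list[tuple[float, float]]

    @property
    def n_variables(self) -> int:
        return len(self.arc_index)

    @property
    def n_constraints(self) -> int:
        return self.a_eq.shape[0]


@dataclass
class FlowSolution:
    """Optimal arc flows with the achieved objective value."""

    flows: dict[tuple[str, str], float]
    objective: float
    status: str
    network: FlowNetwork = field(repr=False)

    @property
    def total_flow(self) -> float:
        src = self.network.source
        return sum(f for (u, _), f in self.flows.items() if u == src)


@dataclass
class FlowSubnetwork:
    """Positive-flow subgraph of a solved network."""

    arcs: dict[tuple[str, str], float]
    network: FlowNetwork = field(repr=False)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for u, v in self.arcs:
            out.add(u)
            out.add(v)
        return out

    @property
    def total_flow(self) -> float:
        src = self.network.source
        return sum(f for (u, _), f in self.arcs.items() if u == src)

    def __len__(self) -> int:
        return len(self.arcs)


def formulate(network: FlowNetwork, gamma: float) -> FlowProblem:
    """Build the LP: conservation per interior node plus source/sink balance."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")

    arc_index = sorted(network.arcs)
    col = {a: i for i, a in enumerate(arc_index)}
    n = len(arc_index)

    costs = np.array([network.arcs[a].cost for a in arc_index], dtype=float)
    for a in network.source_arcs():
        costs[col[a]] -= gamma

    interior = sorted(
        nid for nid, kind in network.node_kind.items()
        if kind in ("gene", "endpoint")
    )
    row_of = {nid: i for i, nid in enumerate(interior)}
    rows, cols, vals = [], [], []
    for (u, v), i in col.items():
        if u in row_of:
            rows.append(row_of[u]); cols.append(i); vals.append(-1.0)  # out
        if v in row_of:
            rows.append(row_of[v]); cols.append(i); vals.append(1.0)  # in
    # source out-flow minus sink in-flow = 0
    balance_row = len(interior)
    for (u, v), i in col.items():
        if u == network.source:
            rows.append(balance_row); cols.append(i); vals.append(1.0)
        if v == network.sink:
            rows.append(balance_row); cols.append(i); vals.append(-1.0)

    a_eq = csr_matrix(
        (vals, (rows, cols)), shape=(len(interior) + 1, n), dtype=float
    )
    b_eq = np.zeros(len(interior) + 1)
    bounds = [(0.0, network.arcs[a].capacity) for a in arc_index]
    return FlowProblem(
        network=network, gamma=gamma, arc_index=arc_index,
        costs=costs, a_eq=a_eq, b_eq=b_eq, bounds=bounds,
    )


def solve(problem: FlowProblem, method: str = "highs-ds") -> FlowSolution:
    """Solve the LP exactly; zero flow is always feasible so this cannot fail
    for well-formed inputs."""
    res = linprog(
        problem.costs,
        A_eq=problem.a_eq,
        b_eq=problem.b_eq,
        bounds=problem.bounds,
        method=method,
    )
    if not res.success:
        raise SolverError(
            f"LP solver returned status {res.status}: {res.message}"
        )
    flows = {a: max(0.0, float(x))
             for a, x in zip(problem.arc_index, res.x)}
    return FlowSolution(
        flows=flows, objective=float(res.fun), status="optimal",
        network=problem.network,
    )


def extract_subnetwork(
    solution: FlowSolution, epsilon: float = DEFAULT_EPSILON
) -> FlowSubnetwork:
    """Keep arcs carrying more than ``epsilon`` flow."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    arcs = {a: f for a, f in solution.flows.items() if f > epsilon}
    return FlowSubnetwork(arcs=arcs, network=solution.network)


def solve_network(
    network: FlowNetwork,
    gamma: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> FlowSubnetwork:
    """Convenience: formulate, solve, and extract in one call."""
    if gamma is None:
        gamma = DEFAULT_GAMMA[network.context]
    return extract_subnetwork(solve(formulate(network, gamma)), epsilon)
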