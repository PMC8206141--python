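"""Meta-subnetworks: shared gene links across many associations.

A meta-subnetwork integrates the per-association subnetworks that share one
fixed entity — one drug against several same-type diseases (MDiODr) or one
disease against several drugs (MDrODi). Each undirected gene–gene edge is
weighted by the fraction of subnetworks containing it, so weights of 1 mark
fully conserved mediating links. Observed sharing is compared against random
meta-subnetworks with matched edge counts by an unpaired rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .decompose import KddaSubnetwork
from .model import GeneNetwork


@dataclass
class MetaSubnetwork:
    """Undirected union graph with sharing-fraction edge weights."""

    weights: dict[tuple[str, str], float]
    n_subnetworks: int
    grouping: str = "MDiODr"

    def weight_values(self) -> np.ndarray:
        return np.array(sorted(self.weights.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class SharingComparison:
    statistic: float
    p_value: float
    observed_weights: np.ndarray
    null_weights: np.ndarray
    degenerate: bool = False


def _edge_sets(subs: list[KddaSubnetwork]) -> list[set[tuple[str, str]]]:
    return [set(s.gene_edges()) for s in subs]


def build_meta(
    subs: list[KddaSubnetwork], grouping: str = "MDiODr"
) -> MetaSubnetwork:
    """Edge weight = (subnetworks containing the gene pair) / n.

    Antiparallel arcs inside one subnetwork count once (gene edges are
    undirected here).
    """
    if len(subs) < 2:
        raise ValueError(
            "a meta-subnetwork needs >= 2 per-association subnetworks"
        )
    n = len(subs)
    counts: dict[tuple[str, str], int] = {}
    for edges in _edge_sets(subs):
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
    weights = {e: k / n for e, k in counts.items()}
    return MetaSubnetwork(weights=weights, n_subnetworks=n, grouping=grouping)


def _meta_from_edge_sets(
    edge_sets: list[set[tuple[str, str]]], grouping: str
) -> MetaSubnetwork:
    n = len(edge_sets)
    counts: dict[tuple[str, str], int] = {}
    for edges in edge_sets:
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
    return MetaSubnetwork(
        weights={e: k / n for e, k in counts.items()},
        n_subnetworks=n, grouping=grouping,
    )


def random_meta(
    gn: GeneNetwork,
    edge_counts: list[int],
    n_reps: int,
    seed: int,
    degree_preserving: bool = False,
    grouping: str = "random",
) -> list[MetaSubnetwork]:
    """Null ensemble: per replicate, draw each subnetwork's edge count
    uniformly without replacement from the gene network, then integrate.

    With ``degree_preserving`` the per-edge sampling probability is
    proportional to the product of endpoint degrees, hedging the uniform
    reading of "the same number of edges".
    """
    pool = sorted(gn.edges)
    for c in edge_counts:
        if c > len(pool):
            raise ValueError(
                f"requested {c} edges but the gene network has only "
                f"{len(pool)}"
            )
    probs = None
    if degree_preserving:
        deg: dict[str, int] = {}
        for a, b in pool:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        raw = np.array([deg[a] * deg[b] for a, b in pool], dtype=float)
        probs = raw / raw.sum()
    rng = np.random.default_rng(seed)
    out: list[MetaSubnetwork] = []
    for _ in range(n_reps):
        edge_sets = []
        for c in edge_counts:
            idx = rng.choice(len(pool), size=c, replace=False, p=probs)
            edge_sets.append({pool[i] for i in idx})
        out.append(_meta_from_edge_sets(edge_sets, grouping))
    return out


def sample_meta_direct(
    gn: GeneNetwork,
    observed: MetaSubnetwork,
    n_reps: int,
    seed: int,
) -> list[MetaSubnetwork]:
    """Alternative null: resample the meta edge set directly (same number of
    meta edges, weights drawn with replacement from the observed weights)."""
    pool = sorted(gn.edges)
    if len(observed) > len(pool):
        raise ValueError("meta-subnetwork larger than the gene network")
    obs_w = observed.weight_values()
    rng = np.random.default_rng(seed)
    out: list[MetaSubnetwork] = []
    for _ in range(n_reps):
        idx = rng.choice(len(pool), size=len(observed), replace=False)
        w = rng.choice(obs_w, size=len(observed), replace=True)
        out.append(MetaSubnetwork(
            weights={pool[i]: float(x) for i, x in zip(idx, w)},
            n_subnetworks=observed.n_subnetworks, grouping="random-direct",
        ))
    return out


def compare_sharing(
    observed: MetaSubnetwork,
    null: list[MetaSubnetwork],
    alternative: str = "greater",
) -> SharingComparison:
    """Unpaired rank-sum (Mann-Whitney U) of observed vs pooled null weights.

    Larger observed weights mean links conserved across associations beyond
    what matched-size random subnetworks produce.
    """
    if not null:
        raise ValueError("null ensemble is empty")
    obs = observed.weight_values()
    nul = np.concatenate([m.weight_values() for m in null])
    if obs.size == 0 or nul.size == 0:
        raise ValueError("cannot compare empty weight distributions")
    pooled = np.concatenate([obs, nul])
    if np.all(pooled == pooled[0]):
        return SharingComparison(
            statistic=float(obs.size * nul.size / 2), p_value=1.0,
            observed_weights=obs, null_weights=nul, degenerate=True,
        )
    res = stats.mannwhitneyu(obs, nul, alternative=alternative)
    return SharingComparison(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        observed_weights=obs, null_weights=nul,
    )
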