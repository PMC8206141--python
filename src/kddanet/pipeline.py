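"""End-to-end run for one query: build, solve, decompose, cluster, write."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

from . import __version__
from .decompose import (
    KddaSubnetwork,
    extract_kdda_subnetwork,
    mcl_cluster,
    rank_genes_by_flow,
)
from .flow import DEFAULT_GAMMA, extract_subnetwork, formulate, solve
from .io import (
    RunConfig,
    write_modules,
    write_ranked_genes,
    write_sif,
    write_subnetwork,
)
from .model import (
    DiseaseGeneTable,
    DrugTargetTable,
    GeneNetwork,
    KddaTable,
    build_flow_network,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    query: str
    gamma: float
    total_flow: float
    subnetworks: dict[str, KddaSubnetwork]  # endpoint -> subnetwork
    ranked: dict[str, list[tuple[str, float]]]
    modules: dict[str, dict[str, int]]


def run_pipeline(
    config: RunConfig,
    query: str,
    gn: GeneNetwork,
    dt: DrugTargetTable,
    dg: DiseaseGeneTable,
    kddas: KddaTable,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Solve one query's flow model and decompose it per association.

    Writes, when ``out_dir`` is given: the global positive-flow subnetwork,
    per-endpoint subnetwork TSV + SIF, ranked genes, MCL module labels, and
    a manifest recording the configuration and versions.
    """
    gamma = config.gamma if config.gamma is not None \
        else DEFAULT_GAMMA[config.context]
    net = build_flow_network(query, config.context, gn, dt, dg, kddas)
    solution = solve(formulate(net, gamma))
    flowsub = extract_subnetwork(solution, config.epsilon)
    if not flowsub.arcs:
        log.info("query %s: optimal flow is zero at gamma=%g "
                 "(empty subnetworks)", query, gamma)

    endpoints = sorted(net.endpoints)
    subs: dict[str, KddaSubnetwork] = {}
    ranked: dict[str, list[tuple[str, float]]] = {}
    modules: dict[str, dict[str, int]] = {}
    for ep in endpoints:
        sub = extract_kdda_subnetwork(flowsub, ep)
        subs[ep] = sub
        ranked[ep] = rank_genes_by_flow(sub) if sub.arcs else []
        modules[ep] = mcl_cluster(sub, config.mcl) if sub.arcs else {}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_subnetwork(flowsub, out / f"{query}.flow_subnetwork.tsv")
        for ep in endpoints:
            stem = out / f"{query}__{ep}"
            write_subnetwork(subs[ep], f"{stem}.subnetwork.tsv")
            write_sif(subs[ep], f"{stem}.subnetwork.sif")
            write_ranked_genes(ranked[ep], f"{stem}.ranked_genes.tsv")
            write_modules(modules[ep], f"{stem}.modules.tsv")
        manifest = {
            "query": query,
            "gamma": gamma,
            "config": config.to_dict(),
            "endpoints": endpoints,
            "total_flow": flowsub.total_flow,
            "versions": {
                "kddanet": __version__,
                "python": platform.python_version(),
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        query=query, gamma=gamma, total_flow=flowsub.total_flow,
        subnetworks=subs, ranked=ranked, modules=modules,
    )
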