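"""Plain-TSV readers and writers binding the pipeline stages together.

All inputs are tab-separated text: gene network ``gene_a  gene_b  weight``,
drug targets ``drug  gene  score``, disease genes ``disease  gene  score``,
associations ``drug  disease[  disease_type]`` and annotations
``gene  term``. A leading header line is auto-detected (non-numeric weight in
the first row, or recognized column names) and skipped. Malformed lines are
reported with their line numbers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .decompose import KddaSubnetwork, MclParams
from .evaluate import AnnotationTable, GoldStandard
from .flow import DEFAULT_EPSILON, FlowSubnetwork
from .meta import MetaSubnetwork
from .model import (
    DiseaseGeneTable,
    DrugTargetTable,
    GeneNetwork,
    KddaTable,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A TSV input file violated its expected shape."""


def _rows(path: str | Path, n_cols: int, optional_last: bool = False):
    """Yield (line_number, fields) validating arity; auto-skip a header."""
    path = Path(path)
    lines = path.read_text().splitlines()
    bad: list[str] = []
    first_data = True
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        lo = n_cols - 1 if optional_last else n_cols
        if not lo <= len(fields) <= n_cols:
            bad.append(f"line {lineno}: expected {n_cols} tab-separated "
                       f"columns, got {len(fields)}")
            continue
        if first_data:
            first_data = False
            if _looks_like_header(fields):
                log.debug("%s: skipping header line %d", path, lineno)
                continue
        yield lineno, fields
    if bad:
        raise ParseError(f"{path}: " + "; ".join(bad))


_HEADER_TOKENS = {
    "gene", "gene_a", "gene_b", "weight", "score", "drug", "disease",
    "disease_type", "term", "target", "flow", "confidence",
}


def _looks_like_header(fields: list[str]) -> bool:
    if all(f.strip().lower() in _HEADER_TOKENS for f in fields):
        return True
    last = fields[-1]
    try:
        float(last)
        return False
    except ValueError:
        # non-numeric trailing value where a weight/score is expected
        return fields[-1].strip().lower() in _HEADER_TOKENS or any(
            f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_gene_network(path: str | Path) -> GeneNetwork:
    gn = GeneNetwork()
    seen: dict[tuple[str, str], int] = {}
    for lineno, (a, b, w) in (
        (ln, f) for ln, f in _rows(path, 3)
    ):
        try:
            weight = float(w)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric weight {w!r}")
        key = (a, b) if a <= b else (b, a)
        if key in seen and gn.edges.get(key) != weight:
            raise ParseError(
                f"{path}: duplicate edge {key} with differing weights on "
                f"lines {seen[key]} and {lineno}")
        try:
            gn.add_edge(a, b, weight)
        except ValueError as e:
            raise ParseError(f"{path}: line {lineno}: {e}") from e
        seen[key] = lineno
    return gn


def _read_scored_pairs(path: str | Path) -> Iterable[tuple[int, str, str, float]]:
    for lineno, (k, g, s) in ((ln, f) for ln, f in _rows(path, 3)):
        try:
            yield lineno, k, g, float(s)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric score {s!r}")


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    dt = DrugTargetTable()
    for lineno, drug, gene, score in _read_scored_pairs(path):
        try:
            dt.add(drug, gene, score)
        except ValueError as e:
            raise ParseError(f"{path}: line {lineno}: {e}") from e
    return dt


def read_disease_genes(path: str | Path) -> DiseaseGeneTable:
    dg = DiseaseGeneTable()
    for lineno, disease, gene, score in _read_scored_pairs(path):
        try:
            dg.add(disease, gene, score)
        except ValueError as e:
            raise ParseError(f"{path}: line {lineno}: {e}") from e
    return dg


def read_kdda(path: str | Path) -> KddaTable:
    table = KddaTable()
    for lineno, fields in _rows(path, 3, optional_last=True):
        drug, disease = fields[0], fields[1]
        dtype = fields[2] if len(fields) == 3 else None
        try:
            table.add(drug, disease, dtype)
        except ValueError as e:
            raise ParseError(f"{path}: line {lineno}: {e}") from e
    return table


def read_annotations(path: str | Path) -> AnnotationTable:
    ann = AnnotationTable()
    for _, (gene, term) in ((ln, f) for ln, f in _rows(path, 2)):
        ann.add(gene, term)
    return ann


def read_tables(
    network: str | Path,
    drug_targets: str | Path,
    disease_genes: str | Path,
    kdda: str | Path,
    annotations: str | Path | None = None,
) -> tuple[GeneNetwork, DrugTargetTable, DiseaseGeneTable, KddaTable,
           AnnotationTable | None]:
    return (
        read_gene_network(network),
        read_drug_targets(drug_targets),
        read_disease_genes(disease_genes),
        read_kdda(kdda),
        read_annotations(annotations) if annotations else None,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_gene_network(gn: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (a, b), w in sorted(gn.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_drug_targets(dt: DrugTargetTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(dt.scores):
            for gene, s in sorted(dt.scores[drug].items()):
                fh.write(f"{drug}\t{gene}\t{s:.10g}\n")


def write_disease_genes(dg: DiseaseGeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for dis in sorted(dg.scores):
            for gene, s in sorted(dg.scores[dis].items()):
                fh.write(f"{dis}\t{gene}\t{s:.10g}\n")


def write_kdda(table: KddaTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug, disease in table.pairs:
            dtype = table.disease_types.get(disease)
            if dtype:
                fh.write(f"{drug}\t{disease}\t{dtype}\n")
            else:
                fh.write(f"{drug}\t{disease}\n")


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.terms):
            for term in sorted(ann.terms[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_subnetwork(
    sub: FlowSubnetwork | KddaSubnetwork, path: str | Path
) -> None:
    """``source_node  target_node  flow`` for the positive-flow arcs."""
    with open(path, "w") as fh:
        for (u, v), f in sorted(sub.arcs.items()):
            fh.write(f"{u}\t{v}\t{f:.10g}\n")


def write_sif(
    sub: FlowSubnetwork | KddaSubnetwork, path: str | Path,
    interaction: str = "flow",
) -> None:
    """SIF export (``node  interaction  node``) for network viewers."""
    with open(path, "w") as fh:
        for (u, v) in sorted(sub.arcs):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def write_ranked_genes(
    ranked: list[tuple[str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tflow_through\trank\n")
        for rank, (gene, f) in enumerate(ranked, start=1):
            fh.write(f"{gene}\t{f:.10g}\t{rank}\n")


def write_modules(labels: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmodule_id\n")
        for gene in sorted(labels):
            fh.write(f"{gene}\t{labels[gene]}\n")


def write_meta(meta: MetaSubnetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (a, b), w in sorted(meta.weights.items()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_truth(truth: Mapping[tuple[str, str], set], path: str | Path) -> None:
    with open(path, "w") as fh:
        for (drug, disease) in sorted(truth):
            for gene in sorted(truth[(drug, disease)]):
                fh.write(f"{drug}\t{disease}\t{gene}\n")


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlabel\tsim_kdtg\tsim_kdrg\n")
        for gene in sorted(gold.positives | gold.negatives):
            label = "positive" if gene in gold.positives else "negative"
            fh.write(f"{gene}\t{label}\t{gold.sim_kdtg[gene]:.10g}"
                     f"\t{gold.sim_kdrg[gene]:.10g}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    context: str = "SDrTDi"
    gamma: float | None = None  # None -> context default (6 / 8)
    epsilon: float = DEFAULT_EPSILON
    mcl: MclParams = field(default_factory=MclParams)
    lls_decay: float = 2.0  # D of the evidence-combination formula
    lls_threshold: float = 1.0  # T, minimum per-dataset LLS retained
    n_perm: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "mcl" in d and isinstance(d["mcl"], Mapping):
            d["mcl"] = MclParams(**d["mcl"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
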