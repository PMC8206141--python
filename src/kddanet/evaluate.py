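"""Evaluation machinery: functional-similarity gold standards and metrics.

True mediating genes are rarely known, so subnetwork genes are labeled by a
permutation scheme: a gene is a positive when its mean functional similarity
to both the drug's known target genes (KDTGs) and the disease's known
related genes (KDRGs) exceeds the 95th percentile of null distributions
built from randomly drawn gene sets of matched sizes. Flow-ranked gene lists
are then scored with ROC / precision-recall curves, and subnetwork gene sets
are tested for category enrichment with a hypergeometric upper tail and
Bonferroni correction.

The pairwise gene functional similarity is the Jaccard index of annotation
term sets, mean-aggregated over a reference gene set; it is injectable so a
different semantic-similarity measure can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import stats
from sklearn import metrics as skm


@dataclass
class AnnotationTable:
    """gene → set of functional term identifiers (opaque strings)."""

    terms: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene: str, term: str) -> None:
        self.terms.setdefault(gene, set()).add(term)

    def of(self, gene: str) -> set[str]:
        return self.terms.get(gene, set())

    def annotated_genes(self) -> set[str]:
        return {g for g, ts in self.terms.items() if ts}


@dataclass
class GoldStandard:
    positives: set[str]
    negatives: set[str]
    sim_kdtg: dict[str, float]
    sim_kdrg: dict[str, float]
    threshold_kdtg: float
    threshold_kdrg: float
    seed: int


# ---------------------------------------------------------------------------
# set arithmetic on known-gene collections
# ---------------------------------------------------------------------------


def overlap_ratio(kdtg: set[str], kdrg: set[str]) -> float:
    """Shared genes over the union of drug-target and disease genes."""
    if not kdtg or not kdrg:
        raise ValueError("overlap ratio undefined for an empty gene set")
    return len(kdtg & kdrg) / len(kdtg | kdrg)


def ktkgs(kdtg: set[str], kdrg: set[str]) -> set[str]:
    """Known true association genes: targets that are also disease genes."""
    return kdtg & kdrg


def ntkgs(pathway_nontargets: set[str], updated_disease_genes: set[str]) -> set[str]:
    """Novel true association genes: held-out pathway genes that reappear in
    an independently curated disease gene set."""
    return pathway_nontargets & updated_disease_genes


# ---------------------------------------------------------------------------
# functional similarity and the permutation gold standard
# ---------------------------------------------------------------------------


def jaccard(a: set[str], b: set[str]) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def functional_similarity(
    gene: str,
    reference: Iterable[str],
    ann: AnnotationTable,
    pairwise: Callable[[set[str], set[str]], float] = jaccard,
) -> float:
    """Mean pairwise term-set similarity of ``gene`` to a reference set."""
    ref = list(reference)
    if not ref:
        raise ValueError("reference gene set is empty")
    gt = ann.of(gene)
    return float(np.mean([pairwise(gt, ann.of(r)) for r in ref]))


def compile_gold_standard(
    sub_genes: set[str],
    kdtg: set[str],
    kdrg: set[str],
    ann: AnnotationTable,
    n_perm: int = 1000,
    seed: int = 0,
    percentile: float = 95.0,
    pairwise: Callable[[set[str], set[str]], float] = jaccard,
) -> GoldStandard:
    """Label subnetwork genes positive/negative by permutation.

    Null similarity distributions are built by redrawing KDTG-sized and
    KDRG-sized gene sets ``n_perm`` times from the annotated universe and
    recomputing every subnetwork gene's mean similarity to each draw; the
    null is pooled across genes (one distribution per reference side, shared
    across the association). A gene is positive iff both of its observed
    similarities exceed the respective null percentile.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable percentiles")
    if not sub_genes:
        raise ValueError("empty subnetwork gene set")
    if not kdtg or not kdrg:
        raise ValueError("empty reference gene set")
    universe = sorted(ann.annotated_genes())
    if len(universe) < max(len(kdtg), len(kdrg)):
        raise ValueError(
            "annotated universe smaller than the reference set sizes"
        )

    genes = sorted(sub_genes)
    sim_t = {g: functional_similarity(g, kdtg, ann, pairwise) for g in genes}
    sim_r = {g: functional_similarity(g, kdrg, ann, pairwise) for g in genes}

    rng = np.random.default_rng(seed)
    null_t = np.empty(n_perm * len(genes))
    null_r = np.empty(n_perm * len(genes))
    for p in range(n_perm):
        rand_t = [universe[i]
                  for i in rng.choice(len(universe), len(kdtg), replace=False)]
        rand_r = [universe[i]
                  for i in rng.choice(len(universe), len(kdrg), replace=False)]
        for j, g in enumerate(genes):
            null_t[p * len(genes) + j] = functional_similarity(
                g, rand_t, ann, pairwise)
            null_r[p * len(genes) + j] = functional_similarity(
                g, rand_r, ann, pairwise)

    thr_t = float(np.percentile(null_t, percentile))
    thr_r = float(np.percentile(null_r, percentile))
    positives = {g for g in genes if sim_t[g] > thr_t and sim_r[g] > thr_r}
    return GoldStandard(
        positives=positives,
        negatives=set(genes) - positives,
        sim_kdtg=sim_t,
        sim_kdrg=sim_r,
        threshold_kdtg=thr_t,
        threshold_kdrg=thr_r,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------


@dataclass
class RankingMetrics:
    auroc: float
    auprc: float
    roc_curve: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    pr_curve: tuple[np.ndarray, np.ndarray]  # (recall, precision)


def roc_pr(
    ranked: Mapping[str, float] | list[tuple[str, float]],
    positives: set[str] | GoldStandard,
) -> RankingMetrics:
    """AUROC / AUPRC of a scored gene list against a positive set.

    AUROC equals the probability a random positive outranks a random
    negative (ties counted half); AUPRC is the step-integrated
    precision-recall area (average precision).
    """
    if isinstance(positives, GoldStandard):
        positives = positives.positives
    items = list(ranked.items()) if isinstance(ranked, Mapping) else list(ranked)
    y = np.array([1 if g in positives else 0 for g, _ in items])
    s = np.array([score for _, score in items], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            "ROC/PR undefined: gold standard has a single class among the "
            "ranked genes"
        )
    auroc = float(skm.roc_auc_score(y, s))
    auprc = float(skm.average_precision_score(y, s))
    fpr, tpr, _ = skm.roc_curve(y, s)
    prec, rec, _ = skm.precision_recall_curve(y, s)
    return RankingMetrics(
        auroc=auroc, auprc=auprc,
        roc_curve=(fpr, tpr), pr_curve=(rec, prec),
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    fold: float
    p_value: float
    p_adjusted: float
    overlap: int


def hypergeom_enrichment(
    sub_genes: set[str],
    category: set[str],
    universe: set[str],
    n_tests: int = 1,
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment with Bonferroni correction.

    fold = (overlap / |subnetwork|) / (|category| / |universe|);
    p = P(X >= overlap) drawing |subnetwork| genes from the universe.
    """
    if not universe or not sub_genes:
        raise ValueError("universe and subnetwork gene sets must be non-empty")
    if not sub_genes <= universe or not category <= universe:
        raise ValueError("subnetwork and category must be subsets of universe")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    k = len(sub_genes & category)
    m, n_cat, n_draw = len(universe), len(category), len(sub_genes)
    expected = n_cat / m
    fold = (k / n_draw) / expected if expected > 0 else float("inf")
    p = float(stats.hypergeom.sf(k - 1, m, n_cat, n_draw))
    return EnrichmentResult(
        fold=fold, p_value=p, p_adjusted=min(1.0, p * n_tests), overlap=k,
    )
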