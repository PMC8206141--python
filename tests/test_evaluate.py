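"""Gold-standard compilation, ranking metrics, and enrichment arithmetic."""

import numpy as np
import pytest

from kddanet.evaluate import (
    AnnotationTable,
    compile_gold_standard,
    functional_similarity,
    hypergeom_enrichment,
    jaccard,
    ktkgs,
    ntkgs,
    overlap_ratio,
    roc_pr,
)

from conftest import auroc_by_pair_counting


class TestSetOperations:
    @pytest.mark.parametrize("a,b,expected", [
        ({"a", "b"}, {"b", "c"}, 1 / 3),
        ({"a"}, {"b"}, 0.0),
        ({"a", "b"}, {"a", "b"}, 1.0),
    ])
    def test_overlap_ratio(self, a, b, expected):
        assert overlap_ratio(a, b) == pytest.approx(expected)

    def test_overlap_ratio_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_ratio(set(), {"a"})

    @pytest.mark.parametrize("a,b,expected", [
        ({"a", "b"}, {"b", "c"}, {"b"}),
        ({"a"}, {"b"}, set()),
        ({"a"}, {"a"}, {"a"}),
    ])
    def test_ktkgs_and_ntkgs_are_intersections(self, a, b, expected):
        assert ktkgs(a, b) == expected
        assert ntkgs(a, b) == expected


class TestFunctionalSimilarity:
    def make_ann(self, terms: dict) -> AnnotationTable:
        ann = AnnotationTable()
        for g, ts in terms.items():
            for t in ts:
                ann.add(g, t)
        return ann

    def test_identical_term_sets_give_one(self):
        ann = self.make_ann({"g": {"t1"}, "r1": {"t1"}, "r2": {"t1"}})
        assert functional_similarity("g", {"r1", "r2"}, ann) == 1.0

    def test_unannotated_gene_scores_zero(self):
        ann = self.make_ann({"r1": {"t1"}})
        assert functional_similarity("ghost", {"r1"}, ann) == 0.0

    def test_single_reference_jaccard(self):
        ann = self.make_ann({"g": {"t1", "t2"}, "r": {"t2", "t3"}})
        assert functional_similarity("g", {"r"}, ann) == pytest.approx(1 / 3)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            functional_similarity("g", set(), AnnotationTable())


def module_annotations(n_genes=30, n_modules=3, seed=0) -> AnnotationTable:
    """Module-coherent annotations: each gene carries its module's terms."""
    rng = np.random.default_rng(seed)
    ann = AnnotationTable()
    per = n_genes // n_modules
    for i in range(n_genes):
        m = i // per
        for t in range(4):
            if rng.random() < 0.9:
                ann.add(f"g{i}", f"m{m}t{t}")
        if rng.random() < 0.1:
            ann.add(f"g{i}", f"m{(m + 1) % n_modules}t0")
    return ann


class TestGoldStandard:
    def test_fully_similar_gene_is_positive_unannotated_is_negative(self):
        # g* shares every term with both references; the rest of the
        # universe is term-disjoint, so every null percentile sits below 1
        ann = AnnotationTable()
        for g in ("gstar", "ref_t", "ref_r"):
            ann.add(g, "shared")
        for i in range(200):
            ann.add(f"bg{i}", f"private{i}")
        ann.terms["gX"] = set()  # unannotated subnetwork gene
        sub = {"gstar", "gX"}
        gold = compile_gold_standard(sub, {"ref_t"}, {"ref_r"}, ann,
                                     n_perm=200, seed=1)
        assert "gstar" in gold.positives
        assert "gX" in gold.negatives
        assert gold.positives | gold.negatives == sub
        assert not gold.positives & gold.negatives

    def test_seed_reproducible(self):
        ann = module_annotations()
        gold1 = compile_gold_standard({"g4", "g13"}, {"g0"}, {"g1"}, ann,
                                      n_perm=150, seed=9)
        gold2 = compile_gold_standard({"g4", "g13"}, {"g0"}, {"g1"}, ann,
                                      n_perm=150, seed=9)
        assert gold1.positives == gold2.positives
        assert gold1.threshold_kdtg == gold2.threshold_kdtg

    def test_matches_sorting_percentile_oracle(self):
        """Independent recomputation: same draws, similarity and percentile
        re-derived by explicit loops and sorted-array interpolation."""
        ann = module_annotations()
        sub, kdtg, kdrg = {"g4", "g5", "g12", "g22"}, {"g0", "g1"}, {"g2"}
        n_perm, seed = 120, 4
        gold = compile_gold_standard(sub, kdtg, kdrg, ann,
                                     n_perm=n_perm, seed=seed)

        def sim(g, ref):
            vals = []
            for r in sorted(ref):
                a, b = ann.of(g), ann.of(r)
                vals.append(len(a & b) / len(a | b) if a and b else 0.0)
            return sum(vals) / len(vals)

        universe = sorted(g for g, ts in ann.terms.items() if ts)
        rng = np.random.default_rng(seed)
        genes = sorted(sub)
        null_t, null_r = [], []
        for _ in range(n_perm):
            rt = [universe[i] for i in
                  rng.choice(len(universe), len(kdtg), replace=False)]
            rr = [universe[i] for i in
                  rng.choice(len(universe), len(kdrg), replace=False)]
            for g in genes:
                null_t.append(sim(g, rt))
                null_r.append(sim(g, rr))

        def pct95(vals):  # linear interpolation on the sorted array
            s = sorted(vals)
            h = (len(s) - 1) * 0.95
            lo = int(h)
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        thr_t, thr_r = pct95(null_t), pct95(null_r)
        expected_pos = {g for g in genes
                        if sim(g, kdtg) > thr_t and sim(g, kdrg) > thr_r}
        assert gold.threshold_kdtg == pytest.approx(thr_t, abs=1e-12)
        assert gold.positives == expected_pos

    def test_raising_percentile_never_adds_positives(self):
        ann = module_annotations()
        sub, kdtg, kdrg = {"g4", "g5", "g12"}, {"g0", "g1"}, {"g2"}
        g95 = compile_gold_standard(sub, kdtg, kdrg, ann, n_perm=150,
                                    seed=2, percentile=95.0)
        g99 = compile_gold_standard(sub, kdtg, kdrg, ann, n_perm=150,
                                    seed=2, percentile=99.0)
        assert g99.positives <= g95.positives

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            compile_gold_standard({"g"}, {"a"}, {"b"}, AnnotationTable(),
                                  n_perm=10, seed=0)


class TestRocPr:
    def test_perfect_separation(self):
        ranked = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5}
        m = roc_pr(ranked, {"a", "b"})
        assert m.auroc == 1.0
        assert m.auprc == 1.0

    def test_all_tied_gives_half(self):
        m = roc_pr({"a": 1.0, "b": 1.0}, {"a"})
        assert m.auroc == pytest.approx(0.5)

    def test_reversed_ranking_complements_auroc(self):
        rng = np.random.default_rng(3)
        scores = {f"g{i}": float(s) for i, s in
                  enumerate(rng.permutation(10))}
        pos = {"g0", "g3", "g7"}
        fwd = roc_pr(scores, pos).auroc
        rev = roc_pr({g: -s for g, s in scores.items()}, pos).auroc
        assert fwd + rev == pytest.approx(1.0)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            scores = {f"g{i}": float(rng.integers(0, 5)) for i in range(n)}
            k = int(rng.integers(1, n))
            pos = set(list(scores)[:k])
            expected = auroc_by_pair_counting(scores, pos)
            assert roc_pr(scores, pos).auroc == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr({"a": 1.0, "b": 0.5}, {"a", "b"})


class TestHypergeomEnrichment:
    def test_printed_toy_case(self):
        universe = {f"u{i}" for i in range(10)}
        category = set(list(universe)[:5])
        sub = set(list(category)[:4])
        res = hypergeom_enrichment(sub, category, universe)
        assert res.fold == pytest.approx(2.0)
        assert res.p_value == pytest.approx(5 / 210)

    def test_overlap_at_expectation_gives_fold_one(self):
        universe = {f"u{i}" for i in range(10)}
        category = set(sorted(universe)[:5])
        sub = {sorted(category)[0], sorted(universe - category)[0]}
        assert hypergeom_enrichment(sub, category, universe).fold == \
            pytest.approx(1.0)

    def test_bonferroni(self):
        universe = {f"u{i}" for i in range(100)}
        category = set(sorted(universe)[:10])
        sub = set(sorted(universe)[:5])
        res1 = hypergeom_enrichment(sub, category, universe, n_tests=1)
        res5 = hypergeom_enrichment(sub, category, universe, n_tests=5)
        assert res5.p_adjusted == pytest.approx(min(1.0, res1.p_value * 5))

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"x"}, {"a"}, {"a", "b"})
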