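"""Evaluation suite: confusion statistics, ROC, operating points,
enrichment, per-class aggregation, and PCA."""

import numpy as np
import pytest
from scipy import stats

from idrlig.metrics import (
    DEFAULT_THRESHOLDS,
    best_threshold,
    confusion_metrics,
    go_enrichment,
    idr_propensity,
    pca_project,
    per_class_tpr,
    report_rounding,
    roc_curve,
    threshold_confusions,
)

from test_network import rank_auc


class TestConfusionMetrics:
    def test_site_predictor_operating_point(self):
        m = confusion_metrics(17, 26, 113, 534)
        assert report_rounding(m.sensitivity) == 0.131
        assert report_rounding(m.specificity) == 0.954
        assert report_rounding(m.precision) == 0.395
        assert report_rounding(m.accuracy) == 0.799
        assert report_rounding(m.f_measure) == 0.197
        assert report_rounding(m.PLR) == 2.817

    def test_morf_operating_point_plr(self):
        assert report_rounding(confusion_metrics(40, 110, 90, 450).PLR) == 1.566

    def test_degenerate_denominators_flagged(self):
        m = confusion_metrics(0, 0, 5, 5)
        assert m.sensitivity == 0.0
        assert m.precision == 0.0
        assert "precision" in m.undefined

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            confusion_metrics(0, 0, 0, 0)

    def test_chi_square_correction_reading(self):
        corrected = confusion_metrics(17, 26, 113, 534).chi2_neglog10p
        uncorrected = confusion_metrics(
            17, 26, 113, 534, continuity_correction=False
        ).chi2_neglog10p
        assert 3.0 <= corrected <= 3.3
        assert uncorrected > 3.4


class TestRocCurve:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_curve(scores, labels).auc == pytest.approx(1.0)

    def test_identical_scores_give_half(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 0] * 5)
        assert roc_curve(scores, labels).auc == pytest.approx(0.5)

    def test_matches_rank_statistic_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            scores = np.round(rng.random(30), 2)
            labels = rng.integers(0, 2, size=30)
            if labels.all() or not labels.any():
                continue
            auc = roc_curve(scores, labels).auc
            assert auc == pytest.approx(rank_auc(scores, labels), abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        transformed = scores ** 3  # strictly monotone on [0, 1]
        a = roc_curve(scores, labels).auc
        b = roc_curve(transformed, labels).auc
        assert a == pytest.approx(b, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))


class TestBestThreshold:
    def test_hand_computed_argmax(self):
        # three thresholds, PLR hand-computed: 0.2 -> (0.9/0.5)=1.8,
        # 0.5 -> (0.6/0.2)=3.0, 0.8 -> (0.3/0.2)=1.5
        matrices = [
            confusion_metrics(9, 5, 1, 5, threshold=0.2),
            confusion_metrics(6, 2, 4, 8, threshold=0.5),
            confusion_metrics(3, 2, 7, 8, threshold=0.8),
        ]
        assert best_threshold(matrices, "plr") == 0.5

    def test_single_threshold(self):
        assert best_threshold([confusion_metrics(1, 1, 1, 1, threshold=0.3)], "plr") == 0.3

    def test_ties_resolve_to_higher_threshold(self):
        matrices = [
            confusion_metrics(5, 5, 5, 5, threshold=0.2),
            confusion_metrics(5, 5, 5, 5, threshold=0.6),
        ]
        assert best_threshold(matrices, "plr") == 0.6

    def test_criteria_agree_on_separable_data(self):
        # binary scores: every positive at 1.0, every negative at 0.0, so
        # both criteria are maximal on the same threshold band and the
        # higher-threshold tie rule picks the same operating point
        scores = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        matrices = threshold_confusions(scores, labels)
        assert best_threshold(matrices, "plr") == best_threshold(matrices, "chi2")


class TestGoEnrichment:
    def corpus(self, n=60, seed=0, dims=4):
        rng = np.random.default_rng(seed)
        vectors = rng.normal(size=(n, dims))
        gene_ids = [f"g{i}" for i in range(n)]
        return vectors, gene_ids

    def test_zero_hits_give_pvalue_one(self):
        vectors, gene_ids = self.corpus()
        annotations = {"g0": {"GO:rare"}}
        results = go_enrichment(
            {"q": vectors[30] + 50.0},  # far from g0
            vectors, gene_ids, annotations, k=10,
        )
        rare = [r for r in results["q"] if r.go_term == "GO:rare"]
        assert not rare or rare[0].pvalue == 1.0

    def test_binomial_tail_matches_exact_summation(self):
        n, x, p = 10, 5, 0.1
        expected = sum(
            stats.binom.pmf(j, n, p) for j in range(x, n + 1)
        )
        assert stats.binom.sf(x - 1, n, p) == pytest.approx(expected, rel=1e-12)
        # and the function reports exactly that tail for a constructed case
        vectors = np.zeros((20, 2))
        vectors[:10] += 0.001 * np.arange(20).reshape(-1, 1)[:10]
        gene_ids = [f"g{i}" for i in range(20)]
        annotations = {f"g{i}": {"GO:x"} for i in range(5)}
        results = go_enrichment({"q": vectors[0]}, vectors, gene_ids, annotations, k=10)
        r = results["q"][0]
        manual = sum(stats.binom.pmf(j, r.neighborhood_size, r.background_rate)
                     for j in range(r.hits, r.neighborhood_size + 1))
        assert r.pvalue == pytest.approx(manual, rel=1e-9)

    def test_query_is_its_own_nearest_neighbor(self):
        vectors, gene_ids = self.corpus()
        annotations = {g: {"GO:a"} for g in gene_ids}
        from idrlig.metrics import _neighborhood

        neighbors = _neighborhood(vectors[7], vectors, gene_ids, set(), 5)
        assert neighbors[0] == "g7"

    def test_exclusions_remove_homologs(self):
        vectors, gene_ids = self.corpus()
        annotations = {g: {"GO:a"} for g in gene_ids}
        from idrlig.metrics import _neighborhood

        neighbors = _neighborhood(vectors[7], vectors, gene_ids, {"g7"}, 5)
        assert "g7" not in neighbors

    def test_uniform_annotations_show_no_spurious_enrichment(self):
        """On null corpora (uniform annotation rates) P-values stay large."""
        pvalues = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vectors = rng.normal(size=(40, 3))
            gene_ids = [f"g{i}" for i in range(40)]
            annotations = {g: {"GO:u"} for g in gene_ids}
            results = go_enrichment(
                {"a": vectors[0], "b": vectors[1]},
                vectors, gene_ids, annotations, k=15,
            )
            pvalues.extend(r.pvalue for rs in results.values() for r in rs)
        assert np.mean(pvalues) >= 0.5

    def test_empty_annotations_rejected(self):
        vectors, gene_ids = self.corpus()
        with pytest.raises(ValueError, match="annotation"):
            go_enrichment({"q": vectors[0]}, vectors, gene_ids, {}, k=5)


class TestPerClassTpr:
    def test_always_positive_class(self):
        scores = np.array([1.0, 1.0])
        labels = np.array([1, 1])
        classes = np.array(["Y", "Y"])
        assert per_class_tpr(scores, labels, classes) == {"Y": 1.0}

    def test_never_positive_class(self):
        scores = np.array([0.0, 0.0])
        labels = np.array([1, 1])
        classes = np.array(["Y", "Y"])
        tpr = per_class_tpr(scores, labels, classes, thresholds=np.array([0.5, 1.0]))
        assert tpr == {"Y": 0.0}

    def test_two_class_hand_tabulation(self):
        thresholds = np.array([0.2, 0.6])
        scores = np.array([0.5, 0.9, 0.1, 0.7])
        labels = np.array([1, 1, 1, 1])
        classes = np.array(["A", "A", "B", "B"])
        # class A: t=0.2 -> TP 2 FN 0; t=0.6 -> TP 1 FN 1  => 3/4
        # class B: t=0.2 -> TP 1 FN 1; t=0.6 -> TP 1 FN 1  => 2/4
        tpr = per_class_tpr(scores, labels, classes, thresholds=thresholds)
        assert tpr == {"A": 0.75, "B": 0.5}


class TestIdrPropensity:
    def test_min_max_scaling(self):
        raw = idr_propensity(
            case_counts={"a": 1, "b": 3, "c": 5},
            total_counts={"a": 10, "b": 10, "c": 10},
            background_rates={"a": 1.0, "b": 1.0, "c": 1.0},
        )
        assert raw == pytest.approx({"a": 0.0, "b": 0.5, "c": 1.0})

    def test_constant_profile_scales_to_zero(self):
        out = idr_propensity(
            {"a": 2, "b": 4}, {"a": 10, "b": 20}, {"a": 1.0, "b": 1.0}
        )
        assert out == {"a": 0.0, "b": 0.0}

    def test_zero_total_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero total"):
            out = idr_propensity(
                {"a": 1, "b": 1}, {"a": 0, "b": 10}, {"a": 1.0, "b": 1.0}
            )
        assert set(out) == {"b"}

    def test_hand_computed_table(self):
        # raw: a=(4/20)/0.1=2.0, b=(3/30)/0.05=2.0 -> constant -> zeros
        out = idr_propensity(
            {"a": 4, "b": 3}, {"a": 20, "b": 30}, {"a": 0.1, "b": 0.05}
        )
        assert out == {"a": 0.0, "b": 0.0}


class TestPca:
    def test_collinear_points_explained_by_pc1(self):
        base = np.array([1.0, 2.0, 3.0])
        vectors = [t * base for t in (0.0, 1.0, 2.0, 3.0)]
        _, _, explained = pca_project(vectors)
        assert explained[0] == pytest.approx(1.0)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(0)
        _, components, _ = pca_project(rng.normal(size=(30, 6)))
        assert abs(components[0] @ components[1]) < 1e-10

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 8))
        coords, components, explained = pca_project(x)
        from sklearn.decomposition import PCA

        oracle = PCA(n_components=2).fit(x)
        for i in range(2):
            sign = np.sign(oracle.components_[i][np.argmax(np.abs(oracle.components_[i]))])
            np.testing.assert_allclose(components[i], sign * oracle.components_[i], atol=1e-8)
        np.testing.assert_allclose(explained, oracle.explained_variance_ratio_, atol=1e-8)

    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            pca_project(np.ones((5, 4)))
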