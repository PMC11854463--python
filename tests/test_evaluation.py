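"""Metrics, ROC/AUC, splits, cross-validation, and the experiment harnesses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import daqugrade as dq
from daqugrade.classify import ModelSpec
from daqugrade.evaluation import (
    ConfusionCounts,
    cross_validate,
    grid_experiment,
    metrics,
    pca_boundary_plot,
    roc_auc,
    segmentation_benchmark,
    stratified_split,
)


def concordance_auc(scores, labels):
    """O(n^2) pairwise-concordance oracle with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_direct_arithmetic(self):
        m = metrics(ConfusionCounts(tp=8, fp=2, fn=2, tn=8))
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)

    def test_zero_denominator_is_flagged_not_raised(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert m.precision == 0.0 and "precision" in m.flags

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestRocAuc:
    def test_perfect_ranking(self):
        points, area = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert area == pytest.approx(1.0)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_constant_scores_give_half(self):
        _, area = roc_auc([0.5] * 10, [1, 0] * 5)
        assert area == pytest.approx(0.5)

    def test_matches_concordance_oracle(self, rng):
        scores = np.round(rng.random(50), 2)   # rounded to force ties
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        _, area = roc_auc(scores, labels)
        assert area == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_concordance_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = np.round(rng.random(n), 1)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        points, area = roc_auc(scores, labels)
        assert area == pytest.approx(concordance_auc(scores, labels), abs=1e-12)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestStratifiedSplit:
    def test_300_balanced_gives_180_60_60(self):
        labels = np.repeat(["P", "F", "S"], 100)
        tr, va, te = stratified_split(labels, seed=0)
        assert (len(tr), len(va), len(te)) == (180, 60, 60)
        for split in (tr, va, te):
            _, counts = np.unique(labels[split], return_counts=True)
            assert (counts == counts[0]).all()

    def test_deterministic_and_exact_partition(self):
        labels = np.repeat([0, 1, 2], 25)
        a = stratified_split(labels, seed=7)
        b = stratified_split(labels, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        merged = np.concatenate(a)
        assert np.array_equal(np.sort(merged), np.arange(len(labels)))

    def test_all_train_ratio(self):
        labels = np.repeat([0, 1], 5)
        tr, va, te = stratified_split(labels, ratios=(1, 0, 0), seed=0)
        assert len(tr) == 10 and len(va) == 0 and len(te) == 0

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_split([0, 0, 0, 1, 1, 1], ratios=(0.5, 0.3, 0.3))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            stratified_split([0, 0, 0, 1, 1])


class TestCrossValidate:
    def test_separable_data_perfect_mean(self, rng):
        from daqugrade.features import FeatureTable

        y = np.array([0, 1] * 20)
        X = rng.normal(0, 0.5, (40, 2))
        X[:, 0] += 8 * y
        table = FeatureTable(matrix=X, labels=y, weights=np.ones(40),
                             feature_names=["a", "b"], layer="L2", task="toy")
        reports, summary = cross_validate(ModelSpec("lr"), table, folds=5, seed=0)
        assert summary["accuracy"]["mean"] == pytest.approx(1.0)
        assert len(reports) == 5

    def test_summary_is_mean_of_folds(self, l2_table):
        reports, summary = cross_validate(ModelSpec("lr"), l2_table, folds=4, seed=1)
        accs = [r.accuracy for r in reports]
        assert summary["accuracy"]["mean"] == pytest.approx(np.mean(accs))

    def test_folds_exceeding_class_size_rejected(self, l2_table):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ModelSpec("lr"), l2_table, folds=50, seed=0)


@pytest.fixture(scope="module")
def bench_corpus():
    images, _ = dq.generate_dataset(8, seed=21)
    return images


class TestSegmentationBenchmark:
    def test_three_methods_three_rows(self, bench_corpus):
        rows = segmentation_benchmark(bench_corpus, seed=0)
        assert len(rows) == 3
        assert {r["method"] for r in rows} == {"threshold", "kmeans", "morph_fusion"}
        for r in rows:
            if not r["flagged"]:
                assert 0 <= r["accuracy"] <= 1
                assert "processing_time_s" in r

    def test_deterministic_metrics(self, bench_corpus):
        a = segmentation_benchmark(bench_corpus, methods=["threshold"], seed=3)
        b = segmentation_benchmark(bench_corpus, methods=["threshold"], seed=3)
        for key in ("accuracy", "precision", "recall", "f1", "auc"):
            assert a[0][key] == b[0][key]

    def test_shadow_hurts_kmeans_more_than_morph_fusion(self):
        from dataclasses import replace

        params = replace(dq.GenParams(), shadow_strength=0.4)
        jaccards = {"kmeans": [], "morph_fusion": []}
        for seed in range(3):
            img = dq.generate_daqu_image("P", params, seed=seed)
            for method in jaccards:
                r = dq.segment(img.pixels, method)
                inter = (r.mask & img.true_mask).sum()
                union = (r.mask | img.true_mask).sum()
                jaccards[method].append(inter / union)
        assert np.mean(jaccards["kmeans"]) < np.mean(jaccards["morph_fusion"])


class TestGridExperiment:
    def test_4x6_grid(self, l2_table):
        matrix, details = grid_experiment(
            l2_table, seed=0,
            selector_config={"rf_mda": {"n_trees": 50},
                             "lasso": {"cv_folds": 4},
                             "ridge": {"cv_folds": 4}},
        )
        assert len(matrix) == 4
        for sel, row in matrix.items():
            assert len(row) == 6
            for acc in row.values():
                assert acc is None or 0 <= acc <= 1

    def test_identity_selector_extends_grid(self, l2_table):
        matrix, _ = grid_experiment(
            l2_table, selectors=["rfe"], models=["lr"], seed=0,
            include_identity=True,
        )
        assert set(matrix) == {"rfe", "identity"}

    def test_deterministic(self, l2_table):
        kw = dict(selectors=["ridge"], models=["lr", "knn"], seed=5,
                  selector_config={"ridge": {"cv_folds": 4}})
        a, _ = grid_experiment(l2_table, **kw)
        b, _ = grid_experiment(l2_table, **kw)
        assert a == b


class TestPcaBoundaryPlot:
    def test_writes_valid_png(self, l2_table, tmp_path):
        out = tmp_path / "boundary.png"
        pca_boundary_plot(l2_table, ModelSpec("lr"), out)
        assert out.exists()
        with open(out, "rb") as fh:
            assert fh.read(8) == b"\x89PNG\r\n\x1a\n"

    def test_pca_scores_centered_and_variance_ordered(self, l2_table):
        from sklearn.decomposition import PCA

        X = l2_table.matrix
        sd = X.std(axis=0)
        sd[sd == 0] = 1
        Z = PCA(n_components=2, random_state=0).fit_transform((X - X.mean(0)) / sd)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert Z[:, 0].var() >= Z[:, 1].var()

    def test_constant_table_rejected(self, tmp_path):
        from daqugrade.features import FeatureTable

        table = FeatureTable(matrix=np.ones((10, 3)), labels=np.array([0, 1] * 5),
                             weights=np.ones(10), feature_names=["a", "b", "c"],
                             layer="L2", task="toy")
        with pytest.raises(ValueError, match="constant"):
            pca_boundary_plot(table, ModelSpec("lr"), tmp_path / "x.png")
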