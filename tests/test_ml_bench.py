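"""Benchmark protocol tests: AUROC against a pair-counting oracle,
stratification and class-weight contracts, leakage-free scaling, and the
behavior of the cross-validated method comparison."""

import numpy as np
import pandas as pd
import pytest

from epitope_ptqsar import ml_bench
from epitope_ptqsar.ml_bench import (
    BenchmarkConfig,
    UndefinedMetricError,
    auroc,
    class_weights,
    rank_feature_importance,
    rf_tree_scan,
    run_benchmark,
    stratified_folds,
)
from epitope_ptqsar.pt_features import FEATURE_COLUMNS, LABEL_COLUMN


def oracle_auroc(scores, labels):
    """All-pairs concordance counting, ties half-credited."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def feature_frame(X, y):
    frame = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    frame[LABEL_COLUMN] = y
    return frame


def threshold_dataset(n, rng, noise=0.0):
    """Deterministic single-feature threshold labels."""
    X = rng.normal(size=(n, len(FEATURE_COLUMNS)))
    y = (X[:, 4] > 0).astype(int)
    if noise:
        flip = rng.random(n) < noise
        y = np.where(flip, 1 - y, y)
    return feature_frame(X, y)


def cluster_dataset(n, rng, margin=2.0):
    """Two widely separated Gaussian clusters: the separable limit for
    every method, including distance-based ones."""
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, len(FEATURE_COLUMNS))) + margin * (2 * y[:, None] - 1)
    return feature_frame(X, y)


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),
            ((0.9, 0.8, 0.2, 0.1), (0, 0, 1, 1), 0.0),
            ((0.9, 0.8, 0.7, 0.6), (1, 0, 1, 0), 0.75),
            ((0.5, 0.5, 0.5, 0.5), (1, 0, 1, 0), 0.5),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auroc(scores, labels) == expected

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            # coarse grid of score values forces plenty of ties
            scores = rng.integers(0, 5, size=n) / 4.0
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == oracle_auroc(scores, labels)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])


class TestStratifiedFolds:
    def test_balanced_tiny_case(self):
        labels = [1] * 5 + [0] * 5
        assignment = stratified_folds(labels, 5, seed=0)
        for fold in range(5):
            members = np.asarray(labels)[assignment == fold]
            assert sorted(members) == [0, 1]

    def test_partition_and_ratio_preservation(self, rng):
        labels = rng.binomial(1, 0.35, size=997)
        assignment = stratified_folds(labels, 5, seed=3)
        assert np.bincount(assignment).sum() == labels.size
        expected = labels.sum() / 5
        for fold in range(5):
            got = labels[assignment == fold].sum()
            assert abs(got - expected) <= 1.0

    def test_deterministic_given_seed(self, rng):
        labels = rng.binomial(1, 0.4, size=200)
        a = stratified_folds(labels, 5, seed=11)
        b = stratified_folds(labels, 5, seed=11)
        c = stratified_folds(labels, 5, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            stratified_folds([1, 1, 1, 0, 0, 0, 0, 0], 5)


class TestClassWeights:
    def test_balanced_closed_form(self):
        w = class_weights([0] * 150 + [1] * 50, "balanced")
        assert w[0] == pytest.approx(200 / 300)
        assert w[1] == pytest.approx(2.0)
        assert w[0] * 150 == pytest.approx(w[1] * 50)

    def test_normalized_mode(self):
        w = class_weights([0] * 150 + [1] * 50, "normalized")
        assert w[0] == 1.0
        assert w[1] == pytest.approx(3.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestRunBenchmark:
    def test_separable_limit_all_methods_near_perfect(self, rng):
        table = cluster_dataset(600, rng)
        results = run_benchmark(table, BenchmarkConfig(seed=0))
        assert len(results) == 7
        for r in results:
            assert r.mean >= 0.99, r.method

    def test_shuffled_labels_give_chance_auroc(self, rng):
        table = threshold_dataset(5000, rng, noise=0.1)
        table[LABEL_COLUMN] = rng.permutation(table[LABEL_COLUMN].to_numpy())
        results = run_benchmark(table, BenchmarkConfig(seed=1))
        for r in results:
            assert abs(r.mean - 0.5) <= 0.03, (r.method, r.mean)

    def test_reproducible_given_seed(self, rng):
        table = threshold_dataset(400, rng, noise=0.2)
        cfg = BenchmarkConfig(methods=("lr", "rf"), seed=5)
        a = run_benchmark(table, cfg)
        b = run_benchmark(table, cfg)
        assert [r.fold_aurocs for r in a] == [r.fold_aurocs for r in b]

    def test_non_finite_feature_reported_with_row(self, rng):
        table = threshold_dataset(100, rng)
        table.loc[17, "d_theta5_seq"] = np.nan
        with pytest.raises(ValueError, match="row 17"):
            run_benchmark(table, BenchmarkConfig(methods=("lr",)))

    def test_scaler_fits_never_include_test_rows(self, rng, monkeypatch):
        table = threshold_dataset(300, rng, noise=0.1)
        sentinel = 1.0e9
        table.loc[42, "q_theta0_org"] = sentinel
        seen = []
        original_fit = ml_bench.StandardScaler.fit

        def spying_fit(self, X, y=None, **kw):
            seen.append(np.asarray(X).copy())
            return original_fit(self, X, y, **kw)

        monkeypatch.setattr(ml_bench.StandardScaler, "fit", spying_fit)
        run_benchmark(table, BenchmarkConfig(methods=("lr",), seed=2))
        contains = [bool((X == sentinel).any()) for X in seen]
        # the sentinel row sits in exactly one test fold, so it must be
        # absent from exactly one of the five training-fold scaler fits
        assert len(seen) == 5
        assert sum(contains) == 4


class TestTreeScanAndImportance:
    def test_single_tree_runs(self, rng):
        table = threshold_dataset(300, rng, noise=0.2)
        results = rf_tree_scan(table, [1], BenchmarkConfig(methods=("rf",), seed=0))
        assert len(results) == 1
        assert all(0.0 <= v <= 1.0 for v in results[0].fold_aurocs)

    def test_default_scan_covers_ten_counts(self):
        assert ml_bench.DEFAULT_TREE_COUNTS == (5, 10, 20, 30, 40, 50, 100, 200, 500, 1000)

    def test_more_trees_do_not_hurt_on_nonlinear_data(self, nonlinear_20k):
        table = nonlinear_20k.features.head(6000)
        results = rf_tree_scan(table, [5, 100], BenchmarkConfig(methods=("rf",), seed=42))
        assert results[1].mean >= results[0].mean

    def test_importances_normalized_and_complete(self, rng):
        table = threshold_dataset(500, rng, noise=0.1)
        ranking, per_fold = rank_feature_importance(
            table, BenchmarkConfig(methods=("rf",), seed=0), n_trees=20,
            return_per_fold=True,
        )
        assert sorted(name for name, _ in ranking) == sorted(FEATURE_COLUMNS)
        np.testing.assert_allclose(per_fold.sum(axis=1), 1.0, atol=1e-9)
        assert (per_fold >= 0).all()
        # the planted single informative feature dominates
        assert ranking[0][0] == "d_theta5_seq"

    def test_empty_tree_counts_rejected(self, rng):
        table = threshold_dataset(100, rng)
        with pytest.raises(ValueError):
            rf_tree_scan(table, [], BenchmarkConfig(methods=("rf",)))


class TestBoxplotReport:
    def test_report_files_and_determinism(self, tmp_path, rng):
        table = threshold_dataset(300, rng, noise=0.2)
        results = run_benchmark(table, BenchmarkConfig(methods=("lr", "dt"), seed=0))
        png, csv_path = ml_bench.boxplot_report(results, tmp_path / "out")
        assert png.exists()
        first = csv_path.read_bytes()
        ml_bench.boxplot_report(results, tmp_path / "out")
        assert csv_path.read_bytes() == first
        header = first.decode().splitlines()[0]
        assert header == "method,fold_1,fold_2,fold_3,fold_4,fold_5,mean,sd"
        body = first.decode().splitlines()[1].split(",")
        folds = np.array([float(v) for v in body[1:6]])
        assert float(body[6]) == pytest.approx(folds.mean(), abs=5e-7)
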