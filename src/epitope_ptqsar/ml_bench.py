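"""Cross-validated AUROC benchmark of seven classifiers on the feature table.

The evaluation protocol: stratified five-fold cross-validation (folds
preserve the ~2:1 class imbalance), per-fold standardization fitted on the
training split only, class weighting for every weight-aware learner, and
AUROC as the sole score (appropriate for imbalanced classes; it equals the
probability that a random positive outscores a random negative, ties
half-credited).

The seven methods compared, at their toolkit defaults unless noted:
k-nearest neighbors (k = 5, unweighted voting — the method has no class
weights, which is logged), linear-kernel SVM, RBF-kernel SVM, logistic
regression, decision tree, random forest (10 trees by default for the
method comparison; the tree count is scanned separately), and XGBoost
gradient-boosted trees (imbalance passed as the positive-class weight
ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .pt_features import FEATURE_COLUMNS, LABEL_COLUMN

__all__ = [
    "DEFAULT_METHODS",
    "DEFAULT_TREE_COUNTS",
    "BenchmarkConfig",
    "BenchmarkResult",
    "UndefinedMetricError",
    "auroc",
    "stratified_folds",
    "class_weights",
    "run_benchmark",
    "rf_tree_scan",
    "rank_feature_importance",
    "boxplot_report",
]

logger = logging.getLogger(__name__)

#: Canonical method keys, in reporting order.
DEFAULT_METHODS = ("knn", "svml", "svmr", "lr", "dt", "rf", "xgb")

METHOD_LABELS = {
    "knn": "KNN",
    "svml": "SVM linear",
    "svmr": "SVM RBF",
    "lr": "LR",
    "dt": "DT",
    "rf": "RF",
    "xgb": "XGB",
}

#: Tree counts of the default random-forest scan.
DEFAULT_TREE_COUNTS = (5, 10, 20, 30, 40, 50, 100, 200, 500, 1000)


class UndefinedMetricError(ValueError):
    """AUROC is undefined when only one class is present."""


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of the cross-validated benchmark.

    ``class_weight_mode`` is ``"balanced"`` (w_c = N / (2 n_c)) or
    ``"normalized"`` (balanced weights rescaled so w_0 = 1; the two are
    proportional and equivalent for every learner here).  A single seed
    drives fold shuffling and all stochastic learners.
    """

    methods: tuple[str, ...] = DEFAULT_METHODS
    n_folds: int = 5
    seed: int = 42
    class_weight_mode: str = "balanced"
    rf_trees: int = 10
    knn_k: int = 5
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.rf_trees < 1:
            raise ValueError(f"rf_trees must be >= 1, got {self.rf_trees}")
        unknown = set(self.methods) - set(DEFAULT_METHODS)
        if unknown:
            raise ValueError(f"unknown method keys: {sorted(unknown)}")


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-fold AUROCs of one method/configuration, with mean and SD."""

    method: str
    fold_aurocs: tuple[float, ...]
    label: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_aurocs))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_aurocs, ddof=1))


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg) over all
    positive-negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "AUROC needs at least one positive and one negative label"
        )
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def stratified_folds(labels: Sequence[int], n_folds: int = 5, seed: int = 42) -> np.ndarray:
    """Shuffled stratified fold assignment, one fold id per instance.

    Folds partition the instances and preserve the class ratio to within
    one instance per fold; deterministic given the seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has {counts.min()} members, fewer than "
            f"{n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


def class_weights(labels: Sequence[int], mode: str = "balanced") -> dict[int, float]:
    """Inverse-frequency class weights for the binary label.

    ``balanced``: w_c = N / (2 n_c), so w_0 n_0 = w_1 n_1.  ``normalized``:
    balanced weights divided by w_0, so w_0 = 1.  Weights are logged at two
    decimals but carried at full precision.
    """
    labels = np.asarray(labels)
    n = labels.size
    n_pos = int((labels == 1).sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("class weights need both classes present")
    weights = {0: n / (2.0 * n_neg), 1: n / (2.0 * n_pos)}
    if mode == "normalized":
        w0 = weights[0]
        weights = {0: 1.0, 1: weights[1] / w0}
    elif mode != "balanced":
        raise ValueError(f"unknown class-weight mode {mode!r}")
    logger.info(
        "class weights (%s): Class 0: %.2f, Class 1: %.2f",
        mode, weights[0], weights[1],
    )
    return weights


def _build_estimator(method: str, weights: Mapping[int, float], cfg: BenchmarkConfig):
    w = dict(weights)
    if method == "knn":
        logger.info("KNN has no class weights; using unweighted voting")
        return KNeighborsClassifier(n_neighbors=cfg.knn_k)
    if method == "svml":
        return SVC(kernel="linear", class_weight=w, random_state=cfg.seed)
    if method == "svmr":
        return SVC(kernel="rbf", class_weight=w, random_state=cfg.seed)
    if method == "lr":
        return LogisticRegression(class_weight=w, max_iter=1000)
    if method == "dt":
        return DecisionTreeClassifier(class_weight=w, random_state=cfg.seed)
    if method == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.rf_trees, class_weight=w, random_state=cfg.seed
        )
    if method == "xgb":
        return XGBClassifier(
            scale_pos_weight=w[1] / w[0],
            random_state=cfg.seed,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown method {method!r}")


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


def _extract_xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in (*FEATURE_COLUMNS, LABEL_COLUMN) if c not in features]
    if missing:
        raise ValueError(f"feature table is missing columns {missing}")
    X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = features[LABEL_COLUMN].to_numpy(dtype=int)
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite feature value at row {bad[0]}")
    return X, y


def _fold_splits(y: np.ndarray, cfg: BenchmarkConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    assignment = stratified_folds(y, cfg.n_folds, cfg.seed)
    splits = []
    for fold in range(cfg.n_folds):
        test = np.flatnonzero(assignment == fold)
        train = np.flatnonzero(assignment != fold)
        for part, name in ((y[train], "training"), (y[test], "test")):
            if np.unique(part).size < 2:
                raise ValueError(
                    f"fold {fold} has a single-class {name} split; "
                    "stratification failed"
                )
        splits.append((train, test))
    return splits


def _evaluate(
    X: np.ndarray,
    y: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    method: str,
    cfg: BenchmarkConfig,
) -> tuple[float, ...]:
    fold_scores = []
    for train, test in splits:
        X_train, X_test = X[train], X[test]
        if cfg.standardize:
            scaler = StandardScaler().fit(X_train)
            X_train = scaler.transform(X_train)
            X_test = scaler.transform(X_test)
        weights = class_weights(y[train], cfg.class_weight_mode)
        est = _build_estimator(method, weights, cfg)
        est.fit(X_train, y[train])
        fold_scores.append(auroc(_scores(est, X_test), y[test]))
    return tuple(fold_scores)


def run_benchmark(
    features: pd.DataFrame, cfg: BenchmarkConfig | None = None
) -> list[BenchmarkResult]:
    """Benchmark every configured method under the shared CV protocol.

    For each fold the standardizer is fitted on the training split only,
    class weights are computed on the training labels, and the held-out
    split is scored by AUROC.  Fully reproducible given the seed.
    """
    cfg = cfg or BenchmarkConfig()
    X, y = _extract_xy(features)
    splits = _fold_splits(y, cfg)
    return [
        BenchmarkResult(m, _evaluate(X, y, splits, m, cfg), label=METHOD_LABELS[m])
        for m in cfg.methods
    ]


def rf_tree_scan(
    features: pd.DataFrame,
    tree_counts: Sequence[int] = DEFAULT_TREE_COUNTS,
    cfg: BenchmarkConfig | None = None,
) -> list[BenchmarkResult]:
    """Random-forest AUROC across tree counts, on identical folds.

    Reusing the same stratified splits for every tree count makes the
    per-fold AUROC differences paired comparisons.
    """
    if not tree_counts or any(t < 1 for t in tree_counts):
        raise ValueError("tree_counts must be non-empty positive integers")
    cfg = cfg or BenchmarkConfig()
    X, y = _extract_xy(features)
    splits = _fold_splits(y, cfg)
    results = []
    for n_trees in tree_counts:
        scan_cfg = replace(cfg, rf_trees=int(n_trees))
        results.append(
            BenchmarkResult(
                "rf",
                _evaluate(X, y, splits, "rf", scan_cfg),
                label=f"RF{n_trees}",
            )
        )
    return results


def rank_feature_importance(
    features: pd.DataFrame,
    cfg: BenchmarkConfig | None = None,
    n_trees: int = 100,
    return_per_fold: bool = False,
):
    """Impurity-based random-forest importances averaged across CV folds.

    Per fold, the forest is fitted on the standardized training split and
    its normalized impurity importances (non-negative, summing to one) are
    collected; the fold average is returned sorted descending.  With
    ``return_per_fold=True`` the raw per-fold importance matrix (folds x
    features, in :data:`FEATURE_COLUMNS` order) is returned as well.
    """
    cfg = replace(cfg or BenchmarkConfig(), rf_trees=n_trees)
    X, y = _extract_xy(features)
    splits = _fold_splits(y, cfg)
    per_fold = []
    for train, _ in splits:
        X_train = X[train]
        if cfg.standardize:
            X_train = StandardScaler().fit_transform(X_train)
        weights = class_weights(y[train], cfg.class_weight_mode)
        forest = _build_estimator("rf", weights, cfg)
        forest.fit(X_train, y[train])
        imp = forest.feature_importances_
        if abs(imp.sum() - 1.0) > 1e-9 or (imp < 0).any():
            raise AssertionError("impurity importances must be a distribution")
        per_fold.append(imp)
    mean_imp = np.mean(per_fold, axis=0)
    order = np.argsort(mean_imp)[::-1]
    ranking = [(FEATURE_COLUMNS[i], float(mean_imp[i])) for i in order]
    if return_per_fold:
        return ranking, np.asarray(per_fold)
    return ranking


def boxplot_report(
    results: Sequence[BenchmarkResult], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a fold-AUROC box plot and its CSV twin.

    One box per result over its fold AUROCs; the CSV lists per-fold values,
    mean and SD at six decimals, so re-running on the same inputs
    reproduces it byte for byte.  Returns (png_path, csv_path).
    """
    if not results:
        raise ValueError("no results to report")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png_path = out_dir / "auroc_boxplot.png"
    csv_path = out_dir / "auroc_by_fold.csv"

    labels = [r.label or r.method for r in results]
    fig, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    ax.boxplot([r.fold_aurocs for r in results], tick_labels=labels)
    ax.set_ylabel("AUROC")
    ax.set_xlabel("method")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)

    n_folds = len(results[0].fold_aurocs)
    header = (
        ["method"] + [f"fold_{i + 1}" for i in range(n_folds)] + ["mean", "sd"]
    )
    lines = [",".join(header)]
    for r in results:
        cells = [r.label or r.method]
        cells += [f"{v:.6f}" for v in r.fold_aurocs]
        cells += [f"{r.mean:.6f}", f"{r.sd:.6f}"]
        lines.append(",".join(cells))
    csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return png_path, csv_path
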