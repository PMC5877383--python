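"""Classifier harness: kNN, ANN, random forest and RBF-SVM with stratified
cross-validation, accuracy, macro F-score and confusion matrices.

Configurations follow common myoelectric-control practice: k = 6 nearest
neighbours; a single-hidden-layer perceptron sized n-2n-4 with sigmoid
units; a 30-tree random forest whose per-node candidate-feature count is
round(log2 d); and a one-versus-all RBF SVM with a small log-spaced C grid
searched inside the training folds.  The ANN uses 5-fold CV (training cost),
all other classifiers 10-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix


def f_score(tp: int, fp: int, fn: int) -> float:
    """F-score = 2 TP / (2 TP + FP + FN)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise ValueError("all-zero counts: F-score undefined")
    return 2 * tp / denom


def rf_node_subset(d: int) -> int:
    """Random-forest per-node candidate feature count s = round(log2 d), >= 1."""
    if d < 2:
        raise ValueError("need at least 2 features")
    return max(1, int(round(np.log2(d))))


@dataclass
class ClassifierConfig:
    """Backend choice and hyperparameters for the harness."""

    kind: str = "svm"  # knn | ann | rf | svm
    knn_k: int = 6
    rf_trees: int = 30
    ann_max_iter: int = 500
    svm_c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    svm_gamma: str | float = "scale"
    svm_grid_folds: int = 3
    cv_folds: int | None = None  # resolved to 5 for ANN, 10 otherwise

    def resolved_folds(self) -> int:
        if self.cv_folds is not None:
            return self.cv_folds
        return 5 if self.kind == "ann" else 10

    def build(self, n_features: int, seed: int = 0):
        """Instantiate the scikit-learn estimator for this configuration."""
        if self.kind == "knn":
            core = KNeighborsClassifier(n_neighbors=self.knn_k)
        elif self.kind == "ann":
            core = MLPClassifier(
                hidden_layer_sizes=(2 * n_features,),
                activation="logistic",
                early_stopping=True,
                max_iter=self.ann_max_iter,
                random_state=seed,
            )
        elif self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.rf_trees,
                max_features=rf_node_subset(max(n_features, 2)),
                random_state=seed,
            )
        elif self.kind == "svm":
            svc = OneVsRestClassifier(SVC(kernel="rbf", gamma=self.svm_gamma))
            if len(self.svm_c_grid) > 1:
                core = GridSearchCV(
                    svc,
                    {"estimator__C": list(self.svm_c_grid)},
                    cv=self.svm_grid_folds,
                    n_jobs=1,
                )
            else:
                svc.estimator.C = self.svm_c_grid[0]
                core = svc
        else:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        return Pipeline([("scale", StandardScaler()), ("clf", core)])


@dataclass
class ClassifierResult:
    """Cross-validated performance: accuracy (%), macro F-score, row-normalized
    confusion matrix (%), and fold bookkeeping."""

    accuracy: float
    f_score: float
    confusion: pd.DataFrame
    classes: list[str]
    per_class_f: dict[str, float]
    fold_metadata: dict = field(default_factory=dict)


def _confusion_counts(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m


def crossval(
    features: FeatureMatrix,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> ClassifierResult:
    """Stratified k-fold cross-validation of one classifier configuration.

    Predictions are pooled across folds before computing accuracy, the
    macro-averaged F-score and the row-normalized confusion matrix, so every
    window contributes exactly once.
    """
    config = config or ClassifierConfig()
    folds = config.resolved_folds()
    classes = features.classes
    counts = {c: int(np.sum(features.labels == c)) for c in classes}
    small = [c for c, n in counts.items() if n < folds]
    if small:
        raise ValueError(f"classes {small} have fewer windows than {folds} folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    x, y = features.values, features.labels
    y_true = np.empty(y.shape, dtype=y.dtype)
    y_pred = np.empty(y.shape, dtype=y.dtype)
    for train, test in skf.split(x, y):
        clf = config.build(features.n_features, seed=seed)
        clf.fit(x[train], y[train])
        y_true[test] = y[test]
        y_pred[test] = clf.predict(x[test])

    m = _confusion_counts(y_true, y_pred, classes)
    acc = 100.0 * np.trace(m) / m.sum()
    per_class = {}
    for i, c in enumerate(classes):
        tp = int(m[i, i])
        fp = int(m[:, i].sum() - tp)
        fn = int(m[i].sum() - tp)
        per_class[c] = f_score(tp, fp, fn) if (2 * tp + fp + fn) else 0.0
    macro_f = float(np.mean(list(per_class.values())))
    confusion = pd.DataFrame(
        100.0 * m / m.sum(axis=1, keepdims=True), index=classes, columns=classes
    )
    return ClassifierResult(
        accuracy=float(acc),
        f_score=macro_f,
        confusion=confusion,
        classes=classes,
        per_class_f=per_class,
        fold_metadata={"folds": folds, "seed": seed, "kind": config.kind},
    )


def window_length_study(
    recording,
    lengths_ms=(125, 250, 500),
    feature_spec=None,
    subset_size: int = 23,
    classifier: ClassifierConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of the full pipeline at several analysis-window lengths.

    For each length: disjoint execution-only segmentation, full feature
    extraction, Fisher-ratio selection of ``subset_size`` features, then
    cross-validated classification (random forest by default).
    """
    from .recording import WindowSpec, segment
    from .features import extract_all
    from .selection import fd_score

    classifier = classifier or ClassifierConfig(kind="rf")
    rows = []
    for ms in lengths_ms:
        windows = segment(recording, WindowSpec(length_s=ms / 1000.0))
        fm = extract_all(
            windows, recording.fs, feature_spec, channel_names=recording.channel_names
        )
        report = fd_score(fm)
        k = min(subset_size, fm.n_features)
        res = crossval(fm.select(report.order[:k]), classifier, seed=seed)
        rows.append(
            {
                "window_ms": ms,
                "n_windows": fm.n_windows,
                "n_features": k,
                "accuracy": res.accuracy,
                "f_score": res.f_score,
            }
        )
    return pd.DataFrame(rows)
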