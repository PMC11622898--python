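"""Repeated stratified classification protocol.

Embeddings are concatenated, split with stratified 70/30 train/test
partitions (10% of train additionally held out for tuning), fed to a
panel of standard classifiers over several seeded repeats, and scored
with accuracy, weighted precision/recall, weighted and macro F1, and
one-vs-rest ROC-AUC, plus training wall time. Run-level differences
between two methods are compared with a Welch two-sample t-test.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .seqio import EmbeddingMatrix, SequenceSet

METRIC_COLUMNS = [
    "accuracy",
    "precision",
    "recall",
    "f1_weighted",
    "f1_macro",
    "roc_auc",
    "train_time",
]

DEFAULT_CLASSIFIERS = ("SVM", "NB", "MLP", "KNN", "RF", "LR", "DT")


def make_classifier(name: str, seed: int):
    """Instantiate one of the panel classifiers by short name."""
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "NB":
        return GaussianNB()
    if name == "MLP":
        return MLPClassifier(random_state=seed, max_iter=300)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "LR":
        return LogisticRegression(random_state=seed, max_iter=1000)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class EvalConfig:
    test_fraction: float = 0.3
    tuning_fraction: float = 0.1
    repeats: int = 5
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    seed: int = 0
    scale_features: bool = True
    roc_average: str = "weighted"

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1) or not (0 < self.tuning_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for name in self.classifiers:
            make_classifier(name, 0)  # validate names eagerly


@dataclass
class EvalResult:
    """Per-(classifier, repeat) metrics plus per-classifier mean/sd."""

    per_run: pd.DataFrame
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        agg = self.per_run.groupby("classifier")[METRIC_COLUMNS].agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        self.summary = agg.reset_index()

    def runs(self, classifier: str, metric: str) -> np.ndarray:
        sel = self.per_run[self.per_run["classifier"] == classifier]
        return sel[metric].to_numpy()


def concat_embeddings(parts: list[EmbeddingMatrix]) -> EmbeddingMatrix:
    """Column-wise concatenation of row-aligned embeddings."""
    if not parts:
        raise ValueError("no embeddings to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.shape[0] != first.shape[0] or p.source_ids != first.source_ids:
            raise ValueError("embeddings are not row-aligned (n or ids differ)")
    return EmbeddingMatrix(
        np.hstack([p.values for p in parts]) if first.shape[0] else
        np.empty((0, sum(p.shape[1] for p in parts))),
        [name for p in parts for name in p.feature_names],
        list(first.source_ids),
    )


def stratified_split(
    sequences: SequenceSet, config: EvalConfig, repeat_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, tune, test) index partition.

    Class proportions are preserved within rounding in every part; the
    result is a deterministic function of (config.seed, repeat_index).
    """
    labels = sequences.labels
    if labels is None:
        raise ValueError("stratified_split requires labeled sequences")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    rare = classes[counts < 2]
    if rare.size:
        raise ValueError(f"class {rare[0]!r} has fewer than 2 members")
    rs = int(config.seed) + int(repeat_index)
    idx = np.arange(sequences.n)
    train_full, test = train_test_split(
        idx, test_size=config.test_fraction, stratify=labels, random_state=rs
    )
    train, tune = train_test_split(
        train_full,
        test_size=config.tuning_fraction,
        stratify=labels[train_full],
        random_state=rs,
    )
    return np.sort(train), np.sort(tune), np.sort(test)


def _prediction_scores(clf, x_test: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Class-membership scores for ROC-AUC, with an indicator fallback."""
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(x_test)
    if hasattr(clf, "decision_function"):
        scores = clf.decision_function(x_test)
        if scores.ndim == 1:  # binary decision function
            return np.column_stack([-scores, scores])
        return scores
    return label_binarize(y_pred, classes=classes).astype(float)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    *,
    classes: np.ndarray | None = None,
    roc_average: str = "weighted",
) -> dict[str, float]:
    """The metric suite for one prediction set.

    Precision/recall/one F1 are support-weighted, the second F1 is macro,
    and ROC-AUC is one-vs-rest over class-membership ``scores`` (indicator
    of the prediction when scores are absent).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(y_true)
    if scores is None:
        scores = label_binarize(y_pred, classes=classes).astype(float)
    y_bin = label_binarize(y_true, classes=classes)
    if len(classes) == 2:
        auc = float(roc_auc_score(y_bin.ravel(), np.asarray(scores)[:, 1]))
    else:
        auc = float(roc_auc_score(y_bin, scores, average=roc_average, multi_class="ovr"))
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, average="weighted", zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, average="weighted", zero_division=0)),
        "f1_weighted": float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
        "f1_macro": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        "roc_auc": auc,
    }


def evaluate(
    embedding: EmbeddingMatrix, sequences: SequenceSet, config: EvalConfig | None = None
) -> EvalResult:
    """Run the repeated stratified protocol on one embedding.

    For each repeat: stratified 70/30 split with a 10%-of-train tuning
    hold-out (reserved, not used by the default fits), optional z-scoring
    fit on train only, then fit/predict/score every configured classifier.
    """
    config = config or EvalConfig()
    labels = sequences.labels
    if labels is None:
        raise ValueError("evaluate requires labeled sequences")
    if embedding.shape[0] != sequences.n:
        raise ValueError("embedding is not row-aligned with the sequence set")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes to evaluate")
    rows = []
    for repeat in range(config.repeats):
        train, _tune, test = stratified_split(sequences, config, repeat)
        x_train, x_test = embedding.values[train], embedding.values[test]
        if config.scale_features:
            scaler = StandardScaler().fit(x_train)
            x_train, x_test = scaler.transform(x_train), scaler.transform(x_test)
        for name in config.classifiers:
            clf = make_classifier(name, config.seed + repeat)
            t0 = time.perf_counter()
            clf.fit(x_train, y[train])
            train_time = time.perf_counter() - t0
            y_pred = clf.predict(x_test)
            scores = _prediction_scores(clf, x_test, y_pred, classes)
            metrics = compute_metrics(
                y[test], y_pred, scores, classes=classes, roc_average=config.roc_average
            )
            rows.append({"classifier": name, "repeat": repeat, **metrics, "train_time": train_time})
    return EvalResult(pd.DataFrame(rows))


def significance_from_runs(metric_a, metric_b) -> float:
    """Two-sided Welch t-test p-value between two sets of run-level metrics.

    Degenerate zero-variance cases follow the conventions p=1 for equal
    constant samples and p=0 for unequal constant samples.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("need two samples of >= 2 finite values")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
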