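"""Classifier evaluation harness for selected feature subsets.

Evaluates a feature subset with four classifiers (KNN, decision tree,
random forest, RBF SVM) under stratified 10-fold cross-validation on the
3-class emotion task or the binary stress task (negative = stress,
neutral/positive = non-stress).

Two cross-validation units are supported: ``pooled_window`` folds over
individual windows (many windows of the same subject can land in both
train and test — optimistic but matching common practice for this kind of
data) and ``grouped_by_subject``, which keeps every subject's windows on
one side of each fold and is the honest default for generalisation claims.
Feature standardisation is fit inside each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import registry
from .selection import discrete_select, pca_reduce, transition_select

CLASSIFIER_NAMES = ("knn", "decision_tree", "random_forest", "svm")
STRESS_STATE = "negative"

SIGNAL_COMBINATIONS = (
    ("ECG",), ("BVP",), ("GSR",),
    ("ECG", "BVP"), ("ECG", "GSR"), ("BVP", "GSR"),
    ("ECG", "BVP", "GSR"),
)


@dataclass
class EvaluationSpec:
    """What to evaluate and how."""

    task: str = "emotion3"                       # emotion3 | stress2
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    folds: int = 10
    cv_mode: str = "grouped_by_subject"          # pooled_window | grouped_by_subject
    signal_combination: tuple[str, ...] = ("ECG", "BVP", "GSR")

    def __post_init__(self) -> None:
        if self.task not in ("emotion3", "stress2"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.classifiers or not self.signal_combination:
            raise ValueError("classifier and signal sets must be non-empty")
        bad = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if bad:
            raise ValueError(f"unknown classifiers: {sorted(bad)}")
        if self.cv_mode not in ("pooled_window", "grouped_by_subject"):
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")


@dataclass
class ClassifierReport:
    """Cross-validated metrics for one evaluation."""

    task: str
    cv_mode: str
    subject_leakage_possible: bool
    metrics: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"classifier": clf, **{k: v for k, v in m.items()
                                       if not isinstance(v, (list, np.ndarray))}}
                for clf, m in self.metrics.items()]
        return pd.DataFrame(rows)


def stress_binarize(labels) -> np.ndarray:
    """Map emotion labels to stress / non-stress."""
    labels = np.asarray(labels, dtype=object)
    known = {"neutral", "negative", "positive"}
    bad = set(labels) - known
    if bad:
        raise ValueError(f"unknown labels: {sorted(map(str, bad))}")
    return np.where(labels == STRESS_STATE, "stress", "non-stress")


def _make_classifier(name: str, seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="auto", random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def evaluate(X, y, spec: EvaluationSpec, seed: int,
             groups=None) -> ClassifierReport:
    """Stratified k-fold evaluation of every classifier in ``spec``.

    Metrics are macro-averaged over classes within each fold, then averaged
    over folds.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < spec.folds:
        raise ValueError("stratification failure: a class has fewer samples than folds")
    if spec.cv_mode == "grouped_by_subject":
        if groups is None:
            raise ValueError("grouped_by_subject mode needs groups")
        cv = StratifiedGroupKFold(n_splits=spec.folds, shuffle=True, random_state=seed)
        split = cv.split(X, y, groups=np.asarray(groups))
    else:
        cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=seed)
        split = cv.split(X, y)
    folds = list(split)
    report = ClassifierReport(spec.task, spec.cv_mode,
                              subject_leakage_possible=spec.cv_mode == "pooled_window")
    for name in spec.classifiers:
        accs, recs, precs, f1s = [], [], [], []
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        for tr, te in folds:
            model = make_pipeline(StandardScaler(), _make_classifier(name, seed))
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            accs.append(accuracy_score(y[te], pred))
            p, r, f1, _ = precision_recall_fscore_support(
                y[te], pred, labels=classes, average="macro", zero_division=0)
            precs.append(p)
            recs.append(r)
            f1s.append(f1)
            conf += confusion_matrix(y[te], pred, labels=classes)
        report.metrics[name] = {
            "accuracy": float(np.mean(accs)),
            "macro_recall": float(np.mean(recs)),
            "macro_precision": float(np.mean(precs)),
            "macro_f1": float(np.mean(f1s)),
            "fold_accuracies": [float(a) for a in accs],
            "confusion": conf.tolist(),
            "classes": classes.tolist(),
        }
    return report


def macro_f1_from_confusion(conf: np.ndarray) -> float:
    """Macro F1 from a confusion matrix (rows = true, cols = predicted)."""
    conf = np.asarray(conf, dtype=float)
    f1s = []
    for k in range(conf.shape[0]):
        tp = conf[k, k]
        fp = conf[:, k].sum() - tp
        fn = conf[k, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return float(np.mean(f1s))


def _emotion_rows(fm: pd.DataFrame) -> pd.DataFrame:
    return fm[fm["label"].isin(["neutral", "negative", "positive"])]


def compare_methods(fm: pd.DataFrame, alpha: float = 0.05,
                    spec: EvaluationSpec | None = None, seed: int = 0,
                    pca_dims: dict[str, int] | None = None,
                    methods: tuple[str, ...] = ("M1", "M2", "M3")) -> dict:
    """Run M1, M2 and M3 end-to-end and evaluate each subset.

    For every signal combination, the features of each method that belong
    to those signals are evaluated; a method selecting no feature for a
    combination yields an ``undefined`` cell and the run continues.
    """
    spec = spec or EvaluationSpec()
    emo = _emotion_rows(fm)
    y = emo["label"].to_numpy()
    if spec.task == "stress2":
        y = stress_binarize(y)
    groups = emo["subject"].to_numpy()

    def subset_cols(selected: list[str], combo: tuple[str, ...]) -> list[str]:
        return [c for c in selected if registry.signal_group(c) in combo]

    results: dict = {"alpha": alpha, "task": spec.task, "methods": {}}
    stat_methods = []
    if "M1" in methods:
        stat_methods.append(("M1", discrete_select(fm, alpha=alpha)))
    if "M3" in methods:
        stat_methods.append(("M3", transition_select(fm, alpha=alpha)))
    for method, sel in stat_methods:
        cells = {}
        for combo in SIGNAL_COMBINATIONS:
            cols = subset_cols(sel.final_subset, combo)
            key = "&".join(combo)
            if not cols:
                cells[key] = {"undefined": True}
                continue
            rep = evaluate(emo[cols], y, spec, seed, groups=groups)
            cells[key] = {"n_features": len(cols), "metrics": rep.metrics}
        results["methods"][method] = {"final_subset": sel.final_subset, "cells": cells}
    if "M2" in methods:
        m2_fm, m2_report = pca_reduce(fm, pca_dims)
        m2_emo = _emotion_rows(m2_fm)
        cells = {}
        for combo in SIGNAL_COMBINATIONS:
            cols = [c for c in m2_emo.columns
                    if c.startswith("PC") and c.rsplit("_", 1)[-1] in combo]
            key = "&".join(combo)
            if not cols:
                cells[key] = {"undefined": True}
                continue
            rep = evaluate(m2_emo[cols], y, spec, seed, groups=groups)
            cells[key] = {"n_features": len(cols), "metrics": rep.metrics}
        results["methods"]["M2"] = {"explained_variance":
                                    {s: r["explained_variance_ratio"]
                                     for s, r in m2_report.items()},
                                    "cells": cells}
    return results
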