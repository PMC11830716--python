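"""Dataset splitting, evaluation and the baseline-classifier harness.

Evaluation follows the study's reporting conventions: the confusion
matrix is expressed as percentages of the *whole* test set (so all 36
cells sum to 100), and ROC/AUC is one-vs-rest per emotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .fcnn import FCNNClassifier


def split_dataset(y, ratio: float = 0.8, seed: int = 0):
    """Stratified train/test indices with a train fraction of ``ratio``.

    1,440 labelled slices split 8:2 give the study's 1,152 / 288.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    y = np.asarray(y)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class EvalReport:
    accuracy: float
    #: 6x6 matrix, cells in percent of the whole test set
    confusion_percent: pd.DataFrame
    #: one-vs-rest AUC per class
    auc: dict[str, float]
    #: class -> (false positive rates, true positive rates)
    roc_points: dict[str, tuple[np.ndarray, np.ndarray]]
    #: per-epoch record copied from the classifier, when available
    history: list[dict] = field(default_factory=list)
    best_epoch: int | None = None


def evaluate(model, X_test, y_test) -> EvalReport:
    """Accuracy, global-percent confusion matrix and per-class ROC/AUC."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(X_test)
    classes = list(model.classes_)
    pred = np.asarray(classes)[proba.argmax(axis=1)]
    acc = float(np.mean(pred == y_test))
    cm = confusion_matrix(y_test, pred, labels=classes)
    cm_pct = pd.DataFrame(100.0 * cm / cm.sum(), index=classes, columns=classes)
    aucs, rocs = {}, {}
    for i, c in enumerate(classes):
        fpr, tpr, _ = roc_curve((y_test == c).astype(int), proba[:, i])
        rocs[c] = (fpr, tpr)
        aucs[c] = float(auc(fpr, tpr))
    return EvalReport(
        accuracy=acc,
        confusion_percent=cm_pct,
        auc=aucs,
        roc_points=rocs,
        history=list(getattr(model, "history_", [])),
        best_epoch=getattr(model, "best_epoch_", None),
    )


def _baselines(seed: int) -> dict:
    return {
        "AdaBoost": AdaBoostClassifier(random_state=seed),
        "GaussianNB": GaussianNB(),
        "GradientBoost": GradientBoostingClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "RandomForest": RandomForestClassifier(random_state=seed),
        "SVM": SVC(probability=True, random_state=seed),
    }

BASELINE_NAMES = ("AdaBoost", "GaussianNB", "GradientBoost", "KNN",
                  "RandomForest", "SVM", "FCNN")


def baseline_compare(X, y, ratio: float = 0.8, seed: int = 0,
                     algorithms=BASELINE_NAMES, epochs: int = 50,
                     hidden_layer_sizes=None) -> pd.DataFrame:
    """Train/test accuracy of the FCNN and six off-the-shelf classifiers.

    ``X`` is expected to be the LDA-reduced feature matrix; the six
    baselines are standard library implementations, the FCNN is this
    package's own network.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    tr, te = split_dataset(y, ratio=ratio, seed=seed)
    avail = _baselines(seed)
    rows = []
    for name in algorithms:
        if name == "FCNN":
            kw = {} if hidden_layer_sizes is None else {
                "hidden_layer_sizes": hidden_layer_sizes}
            clf = FCNNClassifier(epochs=epochs, random_state=seed, **kw)
            clf.fit(X[tr], y[tr], eval_set=(X[te], y[te]))
        elif name in avail:
            clf = avail[name]
            clf.fit(X[tr], y[tr])
        else:
            raise ValueError(f"unknown algorithm {name!r}")
        rows.append(
            {
                "algorithm": name,
                "train_accuracy": float(np.mean(clf.predict(X[tr]) == y[tr])),
                "test_accuracy": float(np.mean(clf.predict(X[te]) == y[te])),
            }
        )
    return pd.DataFrame(rows)
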