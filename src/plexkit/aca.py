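"""Amplification-curve-analysis (ACA) classification and assay evaluation.

Targets are classified from standardized kinetic features of a single
fluorescent channel.  The default model is k-nearest-neighbours (k=5)
behind a pluggable interface: ACA performance here is driven by cluster
separability in feature space, and k-NN is deterministic and
assumption-light.  Evaluation schemes:

* stratified k-fold cross-validation (default k=30);
* leave-one-concentration-out (LOCO), which holds out every template
  concentration in turn and so probes robustness to concentration shift;
* panel-ensemble voting, which combines all well-level predictions of a
  digital-PCR panel into one sample-level majority call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .selection import mean_silhouette

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "train_classifier",
    "cross_validate",
    "loco_evaluate",
    "panel_ensemble",
]


@dataclass
class ClassifierConfig:
    model: str = "knn"
    n_neighbors: int = 5

    def build(self):
        if self.model != "knn":
            raise ValueError(f"unknown model {self.model!r}")
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("knn", KNeighborsClassifier(n_neighbors=self.n_neighbors)),
            ]
        )


@dataclass
class ClassifierReport:
    accuracy: float
    confusion: pd.DataFrame  # rows true, columns predicted
    per_fold_accuracies: list[float]
    scheme: str
    embedding_mss: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = self.confusion.to_numpy().sum()
        trace = np.trace(self.confusion.to_numpy())
        if total and abs(self.accuracy - trace / total) > 1e-12:
            raise ValueError("accuracy inconsistent with confusion matrix")


def _check_training_set(labels: np.ndarray, min_per_class: int = 2) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 classes")
    small = uniq[counts < min_per_class].tolist()
    if small:
        raise ValueError(f"class(es) with < {min_per_class} samples: {small}")


def train_classifier(features, labels, config: ClassifierConfig | None = None):
    """Fit the configured classifier; deterministic for a fixed input."""
    config = config or ClassifierConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_training_set(y)
    return config.build().fit(x, y)


def _aggregate(y_true, y_pred, fold_acc, scheme, classes,
               x=None, y_all=None, warnings_=None) -> ClassifierReport:
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    conf = pd.DataFrame(cm, index=classes, columns=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    mss = None
    if x is not None and y_all is not None:
        x_std = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
        mss = mean_silhouette(x_std, np.asarray(y_all))
    return ClassifierReport(
        accuracy=accuracy,
        confusion=conf,
        per_fold_accuracies=fold_acc,
        scheme=scheme,
        embedding_mss=mss,
        warnings=warnings_ or [],
    )


def cross_validate(
    features, labels, k: int = 30, seed: int = 0, config: ClassifierConfig | None = None
) -> ClassifierReport:
    """Stratified k-fold CV; out-of-fold predictions fill one confusion matrix."""
    config = config or ClassifierConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_training_set(y)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count {counts.min()}; use a smaller k"
        )
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_true_all, y_pred_all, fold_acc = [], [], []
    for train_idx, test_idx in skf.split(x, y):
        model = config.build().fit(x[train_idx], y[train_idx])
        pred = model.predict(x[test_idx])
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
        fold_acc.append(float(np.mean(pred == y[test_idx])))
    return _aggregate(
        np.concatenate(y_true_all), np.concatenate(y_pred_all),
        fold_acc, "kfold", classes, x=x, y_all=y,
    )


def loco_evaluate(
    features, labels, concentration_labels, seed: int = 0,
    config: ClassifierConfig | None = None,
) -> ClassifierReport:
    """Leave-one-concentration-out: one fold per concentration group."""
    config = config or ClassifierConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    conc = np.asarray(concentration_labels)
    groups = np.unique(conc)
    if groups.size < 2:
        raise ValueError("LOCO needs >= 2 concentration groups")
    classes = np.unique(y)
    y_true_all, y_pred_all, fold_acc, warn = [], [], [], []
    for g in groups:
        test = conc == g
        train = ~test
        missing = set(y[test]) - set(y[train])
        if missing:
            warn.append(
                f"concentration {g!r}: class(es) {sorted(missing)} absent from training"
            )
        model = config.build().fit(x[train], y[train])
        pred = model.predict(x[test])
        y_true_all.append(y[test])
        y_pred_all.append(pred)
        fold_acc.append(float(np.mean(pred == y[test])))
    return _aggregate(
        np.concatenate(y_true_all), np.concatenate(y_pred_all),
        fold_acc, "loco", classes, x=x, y_all=y, warnings_=warn,
    )


def panel_ensemble(predictions: pd.DataFrame) -> pd.DataFrame:
    """Majority vote per panel; ties broken by the lowest class label.

    ``predictions`` needs columns ``panel_id`` and ``predicted``; an
    optional ``true`` column adds a correctness flag per panel.  Returns
    one row per panel with the majority call.
    """
    if predictions.empty:
        raise ValueError("no predictions to ensemble")
    if predictions["panel_id"].isna().any():
        raise ValueError("every prediction needs a panel id")
    rows = []
    for panel, grp in predictions.groupby("panel_id", sort=True):
        counts = grp["predicted"].value_counts()
        top = counts[counts == counts.max()].index
        call = sorted(top)[0]  # deterministic tie-break: lowest label
        row = {"panel_id": panel, "call": call, "n_wells": len(grp)}
        if "true" in grp.columns:
            truths = grp["true"].unique()
            row["true"] = truths[0] if len(truths) == 1 else None
            row["correct"] = bool(row["true"] == call) if row["true"] is not None else None
        rows.append(row)
    return pd.DataFrame(rows)
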