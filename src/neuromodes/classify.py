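"""Condition-group (consciousness-state) classification from input patterns.

Features are the per-subject selected B vectors of the four leading matched
components, concatenated (length 4n).  Within every training fold the
predictors are z-scored, reduced by PCA retaining 95% of the variance, and
fed to a linear one-vs-rest SVM; evaluation is stratified five-fold
cross-validation with per-class ROC curves built from the signed decision
values of held-out observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import DataError, DimensionError, DomainError
from .input_patterns import ComponentReport

__all__ = ["FeatureTable", "ClassificationReport", "build_features", "train_and_validate"]


@dataclass(frozen=True)
class FeatureTable:
    """One row per subject x state; features concatenate the selected
    input-map vectors of the matched leading components."""

    X: np.ndarray
    y: np.ndarray  # state label per row
    subjects: np.ndarray  # subject index per row

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise DimensionError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise DataError("feature table contains non-finite entries")
        if len(self.y) != X.shape[0] or len(self.subjects) != X.shape[0]:
            raise DimensionError("labels/subjects do not match feature rows")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", np.asarray(self.y))
        object.__setattr__(self, "subjects", np.asarray(self.subjects))


def build_features(reports: list[ComponentReport]) -> FeatureTable:
    """Assemble the table from per-component reports (components in order).

    Rows are ordered deterministically by (subject, state); every report
    must cover the same states with the same subject counts.
    """
    if not reports:
        raise DataError("need at least one component report")
    states = sorted(reports[0].selected_by_state.keys())
    n_subj = reports[0].selected_by_state[states[0]].shape[0]
    for rep in reports:
        for st in states:
            if st not in rep.selected_by_state:
                raise DataError(f"component {rep.component} is missing state {st!r}")
            if rep.selected_by_state[st].shape[0] != n_subj:
                raise DataError(
                    f"component {rep.component}, state {st!r}: inconsistent subject count"
                )
    rows, labels, subjects = [], [], []
    for s in range(n_subj):
        for st in states:
            rows.append(np.concatenate([rep.selected_by_state[st][s] for rep in reports]))
            labels.append(st)
            subjects.append(s)
    return FeatureTable(X=np.asarray(rows), y=np.asarray(labels), subjects=np.asarray(subjects))


@dataclass(frozen=True)
class ClassificationReport:
    cv_accuracy: float  # percent
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    per_class_rates: pd.DataFrame  # true-positive / false-negative rates
    roc: dict[str, dict]  # class -> {fpr, tpr, auc}
    fold_of_row: np.ndarray
    predictions: np.ndarray
    seed: int
    classes: tuple[str, ...]
    _fold_models: list[Pipeline] = field(default_factory=list, repr=False)


def train_and_validate(
    table: FeatureTable,
    folds: int = 5,
    variance_target: float = 0.95,
    C: float = 1.0,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold cross-validated linear SVM with in-fold PCA.

    Scaling and PCA are fit on each training fold only (no leakage into the
    held-out fold).  Accuracy, the confusion matrix and per-class ROC/AUC
    are aggregated over held-out predictions.
    """
    if not (0.0 < variance_target <= 1.0):
        raise DomainError("variance_target must lie in (0, 1]")
    X, y = table.X, table.y
    classes = np.unique(y)
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        lacking = counts[counts < folds].index.tolist()
        raise DataError(f"classes {lacking} have fewer observations than folds={folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    preds = np.empty(len(y), dtype=object)
    scores = np.zeros((len(y), len(classes)))
    fold_of_row = np.full(len(y), -1, dtype=int)
    models: list[Pipeline] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        # PCA cannot keep more components than min(#train samples, #features)
        ncomp = variance_target if variance_target < 1.0 else min(len(tr) - 1, X.shape[1])
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("pca", PCA(n_components=ncomp, svd_solver="full")),
                ("svm", LinearSVC(C=C, multi_class="ovr")),
            ]
        )
        pipe.fit(X[tr], y[tr])
        preds[te] = pipe.predict(X[te])
        dec = pipe.decision_function(X[te])
        if dec.ndim == 1:  # binary: expand to two signed columns
            dec = np.column_stack([-dec, dec])
        col = {c: i for i, c in enumerate(pipe.classes_)}
        for i, c in enumerate(classes):
            scores[te, i] = dec[:, col[c]]
        fold_of_row[te] = fold
        models.append(pipe)
    preds = preds.astype(str)
    acc = 100.0 * float(np.mean(preds == y))
    cm = confusion_matrix(y, preds, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    with np.errstate(invalid="ignore"):
        tpr_class = np.diag(cm) / cm.sum(axis=1)
    rates = pd.DataFrame(
        {"true_positive_rate": tpr_class, "false_negative_rate": 1.0 - tpr_class}, index=classes
    )
    roc: dict[str, dict] = {}
    for i, c in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == c).astype(int), scores[:, i])
        roc[str(c)] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return ClassificationReport(
        cv_accuracy=acc,
        confusion=confusion,
        per_class_rates=rates,
        roc=roc,
        fold_of_row=fold_of_row,
        predictions=preds,
        seed=int(seed),
        classes=tuple(str(c) for c in classes),
        _fold_models=models,
    )
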