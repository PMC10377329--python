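"""Cross-validated pairwise classification and confusion-matrix metrics.

Stratified k-fold (default 10) cross-validation of two-group diagnostic
classification.  Within every fold, feature selection (top-k columns by
absolute Welch t-statistic between the two training groups) and feature
standardization are computed on the training subjects only, so no
information from the held-out fold leaks into the model.

Metrics follow the standard definitions

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

with the positive class taken as the more-impaired group (severity order
CN < MCI < AD), so sensitivity reads "impaired subjects correctly
detected".  A literal ``as_printed`` mode, in which sensitivity and
specificity share the full denominator TP+TN+FP+FN, is retained for
auditability; it makes sensitivity + specificity equal accuracy and is not
used for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import melm
from .errors import ValidationError

logger = logging.getLogger(__name__)

SEVERITY = {"CN": 0, "MCI": 1, "AD": 2}


class UndefinedMetricError(ValueError):
    """A fold has no members of one class, so a rate is undefined."""


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_label: str

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
                "positive_label": self.positive_label}


def metrics(cm: ConfusionMatrix, as_printed: bool = False) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from a confusion matrix."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    if as_printed:
        return accuracy, cm.tp / cm.total, cm.tn / cm.total
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive examples; sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no negative examples; specificity undefined")
    return accuracy, cm.tp / (cm.tp + cm.fn), cm.tn / (cm.tn + cm.fp)


def select_features(train_features: np.ndarray, train_labels: Sequence[str],
                    k: int) -> np.ndarray:
    """Top-k feature columns by absolute Welch t-statistic on the training set.

    Ties (including all-nan statistics from zero-variance columns, treated
    as 0) resolve to the lower column index.
    """
    x = np.asarray(train_features, dtype=float)
    labels = np.asarray(train_labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > x.shape[1]:
        raise ValidationError(f"k={k} exceeds feature dimension {x.shape[1]}")
    ga = x[labels == classes[0]]
    gb = x[labels == classes[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("each class needs >= 2 training samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(ga, gb, axis=0, equal_var=False)
    score = np.abs(np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=np.inf))
    order = np.argsort(-score, kind="stable")  # stable: ties keep lower index
    return np.sort(order[:k])


def stratified_kfold(labels: Sequence[str], k: int = 10,
                     seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds; per-class counts across folds differ by <= 1."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


@dataclass
class CVReport:
    task: tuple[str, str]
    measure: str
    n_features: int
    per_fold: list[ConfusionMatrix]
    accuracy: float
    sensitivity: float
    specificity: float
    seed: int
    n_subjects: int = 0

    def to_dict(self) -> dict:
        return {
            "task": list(self.task),
            "measure": self.measure,
            "n_features": self.n_features,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_fold": [cm.to_dict() for cm in self.per_fold],
        }


def positive_label_for(task: Sequence[str]) -> str:
    """The more-impaired group of the pair (severity CN < MCI < AD)."""
    if all(t in SEVERITY for t in task):
        return max(task, key=lambda t: SEVERITY[t])
    return task[1]


def run_cv(
    features: np.ndarray,
    labels: Sequence[str],
    task: tuple[str, str],
    measure: str,
    n_features_grid: Sequence[int],
    melm_cfg: melm.MELMConfig,
    seed: int = 0,
    k_folds: int = 10,
) -> list[CVReport]:
    """Stratified k-fold CV over a grid of feature counts; one report each."""
    if len(set(task)) != 2:
        raise ValidationError("task must name two distinct labels")
    labels = np.asarray(labels)
    mask = np.isin(labels, list(task))
    x = np.asarray(features, dtype=float)[mask]
    y = labels[mask]
    present = set(y.tolist())
    if present != set(task):
        raise ValidationError(f"cohort lacks task groups: have {sorted(present)}")
    pos = positive_label_for(task)
    neg = task[0] if task[1] == pos else task[1]
    folds = stratified_kfold(y, k=k_folds, seed=seed)
    reports = []
    for n_feat in n_features_grid:
        per_fold: list[ConfusionMatrix] = []
        for fold_idx, (tr, te) in enumerate(folds):
            try:
                sel = select_features(x[tr], y[tr], n_feat)
                model = melm.fit(x[tr][:, sel], y[tr].tolist(), melm_cfg,
                                 class_order=[neg, pos])
                pred = melm.predict(model, x[te][:, sel])
            except ValidationError as exc:
                raise ValidationError(f"fold {fold_idx}: {exc}") from exc
            truth = y[te]
            tp = int(np.sum((truth == pos) & (np.asarray(pred) == pos)))
            fn = int(np.sum((truth == pos) & (np.asarray(pred) == neg)))
            tn = int(np.sum((truth == neg) & (np.asarray(pred) == neg)))
            fp = int(np.sum((truth == neg) & (np.asarray(pred) == pos)))
            per_fold.append(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn,
                                            positive_label=pos))
        accs, sens, specs = [], [], []
        for fold_idx, cm in enumerate(per_fold):
            accs.append((cm.tp + cm.tn) / cm.total)
            try:
                _, se, sp = metrics(cm)
                sens.append(se)
                specs.append(sp)
            except UndefinedMetricError as exc:
                logger.warning("fold %d excluded from rate averaging: %s",
                               fold_idx, exc)
        reports.append(CVReport(
            task=tuple(task), measure=measure, n_features=int(n_feat),
            per_fold=per_fold,
            accuracy=float(np.mean(accs)),
            sensitivity=float(np.mean(sens)) if sens else float("nan"),
            specificity=float(np.mean(specs)) if specs else float("nan"),
            seed=seed, n_subjects=int(mask.sum()),
        ))
    return reports
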