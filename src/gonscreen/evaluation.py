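"""Evaluation battery: confusion-matrix metrics, ROC/AUC with bootstrap CI,
stratified splitting, and stratified k-fold cross-validation.

Glaucoma is the positive class throughout.  Metrics are computed over gradable
images only; images rejected by the ROI validity filter are counted separately
as ``n_excluded_roi`` and never enter the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .synthetic import GLAUCOMA


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        pos_t, pos_p = y_true == GLAUCOMA, y_pred == GLAUCOMA
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None
    auc_ci_low: float | None = None
    auc_ci_high: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    n_excluded_roi: int = 0
    confusion: ConfusionMatrix | None = None


def compute_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); accuracy is the count of correct
    classifications of both classes over all evaluated images.  An undefined
    ratio (empty denominator) is reported as NaN, never a silent zero."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else float("nan")
    return accuracy, sensitivity, specificity


def stratified_split(
    manifest: pd.DataFrame, train_fraction: float, seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class train/test split with largest-remainder rounding.

    Each class contributes ``round-to-allocation(train_fraction * n_class)``
    rows to the training set; allocation uses the largest-remainder rule so
    class totals sum to ``round(train_fraction * n)``.  Seeded shuffle; the
    returned manifests are disjoint and cover the input exactly.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = manifest[label_col].unique()
    n_train_total = int(round(train_fraction * len(manifest)))
    # largest-remainder allocation of the train quota across classes
    quotas = {c: train_fraction * (manifest[label_col] == c).sum() for c in classes}
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftover = n_train_total - sum(base.values())
    by_rem = sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)
    for c in by_rem[:leftover]:
        base[c] += 1
    train_parts, test_parts = [], []
    for c in classes:
        rows = manifest[manifest[label_col] == c]
        order = rng.permutation(len(rows))
        take = base[c]
        train_parts.append(rows.iloc[order[:take]])
        test_parts.append(rows.iloc[order[take:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def kfold_cv(manifest: pd.DataFrame, k: int, seed: int, train_fn, eval_fn,
             label_col: str = "label"):
    """Stratified k-fold cross-validation (k=5 gives the 80-20 per-fold split).

    Validation folds are disjoint and cover the manifest exactly once,
    stratified within one sample per class per fold.  Per fold, ``train_fn``
    is called on the training rows and ``eval_fn(model, validation_rows)``
    must return a dict with at least ``accuracy``.  Returns
    ``(per_fold_results, best_fold_index)`` where best is the fold with the
    highest validation accuracy.
    """
    y = manifest[label_col].to_numpy()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(np.bincount(pd.factorize(y)[0])):
        raise ValueError("k exceeds the size of the smallest class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = train_fn(manifest.iloc[tr])
        metrics = dict(eval_fn(model, manifest.iloc[va]))
        metrics.update(fold=fold, val_indices=va)
        results.append(metrics)
    best = int(np.argmax([r["accuracy"] for r in results]))
    return results, best


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0):
    """ROC curve, trapezoid AUC, and a stratified-bootstrap 95% CI.

    ``scores`` are p(glaucoma); ties are handled by the simultaneous-threshold
    convention of the ROC sweep.  Returns an :class:`EvalReport` with only the
    ROC fields populated (accuracy fields NaN).
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == GLAUCOMA).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes required for ROC")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))

    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
    boots = []
    for _ in range(n_boot):
        p = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        n = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([p, n])
        f, t, _ = roc_curve(y[idx], scores[idx])
        boots.append(np.trapezoid(t, f))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EvalReport(
        accuracy=float("nan"), sensitivity=float("nan"), specificity=float("nan"),
        auc=auc, auc_ci_low=float(lo), auc_ci_high=float(hi),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )


def evaluate_decisions(y_true, y_pred, scores=None, n_excluded_roi: int = 0,
                       n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Full report from final labels (and optionally p_glaucoma scores)."""
    cm = ConfusionMatrix.from_labels(y_true, y_pred)
    acc, sens, spec = compute_metrics(cm)
    report = EvalReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        n_excluded_roi=n_excluded_roi, confusion=cm)
    if scores is not None and len(np.unique(np.asarray(y_true))) == 2:
        roc = roc_auc(scores, y_true, n_boot=n_boot, seed=seed)
        report.auc = roc.auc
        report.auc_ci_low = roc.auc_ci_low
        report.auc_ci_high = roc.auc_ci_high
        report.roc_points = roc.roc_points
    return report
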