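"""Cross-validation and the binary-classification metric suite.

For each class the metrics are computed one-vs-rest from confusion
counts at a decision-score threshold (0 by default):

* sensitivity Sn = TP/(TP+FN) x 100 — also reported as *coverage*, the
  fraction of true class members recovered (the two are numerically
  identical by definition);
* specificity Sp = TN/(TN+FP) x 100;
* accuracy Acc = (TP+TN)/total x 100;
* Matthews correlation coefficient
  MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
  defined as 0 when any denominator factor is 0;
* ROC-AUC, threshold-independent, computed by the trapezoidal rule over
  the full ROC curve (equivalently the pairwise rank statistic
  P(score+ > score-) + 0.5 P(tie)).

Cross-validation is stratified five-fold: folds are drawn once over the
eight-class labels (so all one-vs-rest problems share the same splits)
and per-fold metrics are arithmetically averaged; a pooled-count mode is
available for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from transpred.constants import CLASS_LABELS
from transpred.model import OneVsRestEnsemble, SvmConfig, predict, train_binary


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    """Per-class performance: percentages plus MCC and (optionally) AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    coverage: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "coverage": self.coverage,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


@dataclass(frozen=True)
class CvPlan:
    """Seeded, stratified fold assignment for five-fold cross-validation."""

    n_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def assign(self, labels: Sequence[str]) -> np.ndarray:
        """Fold index per example; per-class sizes differ by <= 1 when stratified."""
        labels = np.asarray(labels)
        folds = np.empty(len(labels), dtype=int)
        if self.stratified:
            skf = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed
            )
            for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
                folds[test_idx] = k
        else:
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(len(labels))
            for k, chunk in enumerate(np.array_split(perm, self.n_folds)):
                folds[chunk] = k
        return folds


def confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.0
) -> ConfusionCounts:
    """Tally confusion counts at a threshold (score >= threshold -> positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) == 0:
        raise ValueError("empty input")
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sn/Sp/Acc/coverage/MCC from confusion counts (AUC not included).

    Degenerate ratios (no positives or no negatives evaluated) yield 0
    for the affected percentage; a zero factor in the MCC denominator
    yields MCC = 0, the random-prediction value.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero examples")
    sn = 100.0 * c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    sp = 100.0 * c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    acc = 100.0 * (c.TP + c.TN) / c.total
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom) if denom else 0.0
    return MetricSet(sn, sp, acc, coverage=sn, mcc=mcc)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC curve over all distinct thresholds and its trapezoidal AUC.

    Returns (points, auc) where points has columns (FPR, TPR). The
    trapezoidal AUC over the full curve equals the rank statistic
    P(score+ > score-) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC analysis requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def cross_validate(
    X: np.ndarray,
    labels: Sequence[str],
    config: SvmConfig | Mapping[str, SvmConfig],
    plan: CvPlan | None = None,
    threshold: float = 0.0,
    pooled: bool = False,
) -> dict:
    """One-vs-rest stratified K-fold cross-validation for all 8 classes.

    For each class, each fold trains a binary SVM (class vs rest) on the
    other folds and scores the held-out fold; per-fold metrics are
    arithmetically averaged (default) or recomputed from pooled counts
    (``pooled=True``). Returns::

        {
          "per_class": {label: MetricSet (averaged)},
          "per_fold": {label: [MetricSet, ...]},
          "average": MetricSet (mean across classes),
          "folds": fold index per example,
        }
    """
    plan = plan or CvPlan()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    counts = {c: int(np.sum(labels == c)) for c in CLASS_LABELS}
    small = [c for c, n in counts.items() if n < plan.n_folds]
    if small:
        raise ValueError(
            f"class(es) smaller than {plan.n_folds} members: {', '.join(small)}"
        )
    folds = plan.assign(labels)
    per_class: dict = {}
    per_fold: dict = {}
    for cls in CLASS_LABELS:
        cfg = config[cls] if isinstance(config, Mapping) else config
        y = (labels == cls).astype(int)
        fold_sets = []
        pooled_scores: list = []
        pooled_y: list = []
        for k in range(plan.n_folds):
            train, test = folds != k, folds == k
            model = train_binary(X[train], y[train], cfg, cls)
            s = model.decision_scores(X[test])
            c = confusion(s, y[test], threshold)
            m = metrics(c)
            _, auc = roc_auc(s, y[test])
            fold_sets.append(MetricSet(**{**m.as_dict(), "auc": auc}))
            pooled_scores.append(s)
            pooled_y.append(y[test])
        per_fold[cls] = fold_sets
        if pooled:
            s_all = np.concatenate(pooled_scores)
            y_all = np.concatenate(pooled_y)
            m = metrics(confusion(s_all, y_all, threshold))
            _, auc = roc_auc(s_all, y_all)
            per_class[cls] = MetricSet(**{**m.as_dict(), "auc": auc})
        else:
            per_class[cls] = _mean_metrics(fold_sets)
    average = _mean_metrics(list(per_class.values()))
    return {
        "per_class": per_class,
        "per_fold": per_fold,
        "average": average,
        "folds": folds,
    }


def _mean_metrics(sets: Sequence[MetricSet]) -> MetricSet:
    fields = ["sensitivity", "specificity", "accuracy", "coverage", "mcc"]
    means = {f: float(np.mean([getattr(m, f) for m in sets])) for f in fields}
    aucs = [m.auc for m in sets if m.auc is not None]
    means["auc"] = float(np.mean(aucs)) if aucs else None
    return MetricSet(**means)


def confusion_matrix_multiclass(
    ensemble: OneVsRestEnsemble, X: np.ndarray, labels: Sequence[str]
) -> pd.DataFrame:
    """8x8 count table: rows = true class, columns = argmax-predicted class."""
    predicted, _ = predict(ensemble, np.asarray(X, dtype=float))
    table = pd.DataFrame(
        0, index=list(CLASS_LABELS), columns=list(CLASS_LABELS), dtype=int
    )
    for true, pred in zip(labels, predicted):
        table.loc[true, pred] += 1
    return table


def metrics_report(per_class: Mapping[str, MetricSet], average: MetricSet) -> pd.DataFrame:
    """Tabular report (one row per class plus an ``average`` row)."""
    rows = {}
    for cls in CLASS_LABELS:
        rows[cls] = per_class[cls].as_dict()
    rows["average"] = average.as_dict()
    return pd.DataFrame(rows).T[
        ["sensitivity", "specificity", "accuracy", "coverage", "mcc", "auc"]
    ]
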