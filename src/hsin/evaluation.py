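"""Confusion matrices, accuracy metrics and repeated stratified CV.

Metrics follow the standard remote-sensing conventions: overall accuracy
OA = trace / N; per-class F = 2PR/(P+R) with precision TP/(TP+FP) and recall
TP/(TP+FN), macro-averaged over classes; Cohen's kappa
(P_o - P_c) / (1 - P_c) with P_o = OA and chance agreement
P_c = sum_i row_i * col_i / N^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import RepeatedStratifiedKFold

from .exceptions import InvalidInputError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "overall_accuracy",
    "f_score",
    "kappa",
    "per_class_accuracy",
    "metrics_report",
    "repeated_stratified_cv",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InvalidInputError("confusion matrix must be square")
        if len(self.class_names) != self.counts.shape[0]:
            raise InvalidInputError("class_names length must match matrix size")
        if (self.counts < 0).any():
            raise InvalidInputError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


@dataclass
class MetricsReport:
    overall_accuracy: float
    f_score: float
    kappa: float
    per_class_accuracy: dict
    n_samples: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "f_score": self.f_score,
            "kappa": self.kappa,
            "per_class_accuracy": self.per_class_accuracy,
            "n_samples": self.n_samples,
            **self.extra,
        }


def confusion_matrix(y_true, y_pred, class_names=None) -> ConfusionMatrix:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise InvalidInputError("empty input")
    if class_names is None:
        class_names = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    else:
        known = set(class_names)
        unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - known
        if unknown:
            raise InvalidInputError(f"labels {sorted(unknown)!r} not in class_names")
    counts = _sk_confusion(y_true, y_pred, labels=list(class_names))
    return ConfusionMatrix(counts, list(class_names))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: the fraction of correctly classified samples."""
    return float(np.trace(cm.counts) / cm.n_samples)


def f_score(cm: ConfusionMatrix, averaging: str = "macro") -> float:
    """Mean per-class F1.  Degenerate classes (no predictions or no truth)
    contribute 0 with a warning."""
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    f = np.zeros_like(tp)
    degenerate = ((tp + fp) == 0) | ((tp + fn) == 0)
    if degenerate.any():
        warnings.warn(
            f"classes {[cm.class_names[i] for i in np.flatnonzero(degenerate)]} "
            "have no predictions or no true samples; F contribution 0",
            UserWarning,
            stacklevel=2,
        )
    ok = ~degenerate & ((2 * tp + fp + fn) > 0)
    f[ok] = 2 * tp[ok] / (2 * tp[ok] + fp[ok] + fn[ok])
    if averaging == "macro":
        return float(f.mean())
    if averaging == "weighted":
        weights = c.sum(axis=1) / cm.n_samples
        return float((f * weights).sum())
    raise InvalidInputError(f"unknown averaging {averaging!r}")


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement."""
    c = cm.counts.astype(np.float64)
    n = c.sum()
    p_o = np.trace(c) / n
    p_c = float((c.sum(axis=1) * c.sum(axis=0)).sum() / n**2)
    if p_c == 1.0:
        return 0.0  # degenerate single-cell matrix: no chance-corrected signal
    return float((p_o - p_c) / (1.0 - p_c))


def per_class_accuracy(cm: ConfusionMatrix) -> dict:
    """Per-class recall d_ii / row_i; empty rows map to NaN (flagged)."""
    c = cm.counts.astype(np.float64)
    rows = c.sum(axis=1)
    out = {}
    for i, name in enumerate(cm.class_names):
        if rows[i] == 0:
            warnings.warn(f"class {name!r} has no true samples", UserWarning,
                          stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = float(c[i, i] / rows[i])
    return out


def metrics_report(cm: ConfusionMatrix, averaging: str = "macro") -> MetricsReport:
    return MetricsReport(
        overall_accuracy=overall_accuracy(cm),
        f_score=f_score(cm, averaging=averaging),
        kappa=kappa(cm),
        per_class_accuracy=per_class_accuracy(cm),
        n_samples=cm.n_samples,
    )


def repeated_stratified_cv(
    patchset,
    model_builder,
    config,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
):
    """Repeated stratified k-fold CV of a model builder on a patch set.

    ``model_builder(input_shape, n_classes) -> ModelSpec``.  Returns
    ``(reports, summary)`` where ``summary`` maps each metric to
    ``(mean, sd)`` over folds.
    """
    from .models import train as _train, predict as _predict

    labels = patchset.labels
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < folds:
        raise InvalidInputError(
            f"smallest class has {counts.min()} patches (< {folds} folds); "
            "use fewer folds"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    input_shape = None
    reports = []
    for k, (train_idx, test_idx) in enumerate(splitter.split(patchset.data, labels)):
        tr, te = patchset.subset(train_idx), patchset.subset(test_idx)
        if input_shape is None:
            sample_shape = tr.data.shape[1:]
            input_shape = sample_shape
        spec = model_builder(input_shape, len(patchset.class_names))
        model = _train(spec, tr.data, tr.labels, config=config)
        _, pred = _predict(model, te.data)
        cm = confusion_matrix(te.labels, pred, class_names=patchset.class_names)
        rep = metrics_report(cm)
        rep.extra["fold"] = k
        reports.append(rep)

    summary = {}
    for metric in ("overall_accuracy", "f_score", "kappa"):
        vals = np.array([getattr(r, metric) for r in reports])
        summary[metric] = (float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else 0.0))
    return reports, summary
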