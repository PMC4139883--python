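"""Jackknife (leave-one-out) cross-validation and per-class metrics.

The jackknife predicts each sequence with a model trained on all the
others: it involves no random sub-sampling, so its result is unique for
a given dataset and configuration. Per-class performance is summarised
by one-vs-rest sensitivity Sn_k = TP/(TP+FN), specificity
Sp_k = TN/(TN+FP) and Matthews correlation

    MCC_k = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

defined as 0 when any factor of the denominator vanishes; overall
accuracy OA is the fraction of all sequences predicted correctly.

Two jackknife modes are provided. "paper" fixes the feature subset in
advance — ranking and selection run once on the full dataset before the
folds, the protocol commonly published with this family of predictors;
its accuracy is optimistically biased because every held-out sequence
contributed to feature selection. "nested" re-ranks inside each fold on
the training remainder only and is the leakage-free estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import LabeledDataset
from .selection import (
    build_count_table_from_counts,
    confidence_levels,
    feature_subset,
)
from .svm import SVMConfig, train


@dataclass
class ConfusionMatrix:
    """K x K integer matrix: rows true class, columns predicted class."""

    matrix: np.ndarray
    classes: list[str]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
    ) -> "ConfusionMatrix":
        m = _sk_confusion(list(y_true), list(y_pred), labels=list(classes))
        return cls(matrix=m.astype(np.int64), classes=list(classes))


@dataclass
class MetricsReport:
    """Per-class Sn/Sp/MCC plus overall accuracy, as a tidy table."""

    per_class: pd.DataFrame  # class, TP, TN, FP, FN, Sn, Sp, MCC
    overall_accuracy: float
    n: int
    macro_sn: float
    macro_sp: float

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="records"),
            "overall_accuracy": self.overall_accuracy,
            "n": self.n,
            "macro_sn": self.macro_sn,
            "macro_sp": self.macro_sp,
        }


def one_vs_rest_counts(
    confusion: ConfusionMatrix, k: str | int
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for class k by marginalising the confusion matrix."""
    if isinstance(k, str):
        if k not in confusion.classes:
            raise ValueError(f"unknown class {k!r}")
        k = confusion.classes.index(k)
    if not 0 <= k < len(confusion.classes):
        raise ValueError(f"class index {k} out of range")
    m = confusion.matrix
    tp = int(m[k, k])
    fn = int(m[k, :].sum()) - tp
    fp = int(m[:, k].sum()) - tp
    tn = confusion.total - tp - fn - fp
    return tp, tn, fp, fn


def _mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def metrics(confusion: ConfusionMatrix) -> MetricsReport:
    """Per-class Sn/Sp/MCC and overall accuracy from a confusion matrix."""
    n = confusion.total
    if n == 0:
        raise ValueError("confusion matrix is empty")
    rows = []
    for k, cls in enumerate(confusion.classes):
        tp, tn, fp, fn = one_vs_rest_counts(confusion, k)
        sn = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        rows.append(
            {"class": cls, "TP": tp, "TN": tn, "FP": fp, "FN": fn,
             "Sn": sn, "Sp": sp, "MCC": _mcc(tp, tn, fp, fn)}
        )
    per_class = pd.DataFrame(rows)
    oa = float(np.trace(confusion.matrix)) / n
    return MetricsReport(
        per_class=per_class,
        overall_accuracy=oa,
        n=n,
        macro_sn=float(per_class["Sn"].mean()),
        macro_sp=float(per_class["Sp"].mean()),
    )


def _check_fold_classes(train_labels: Sequence[str], classes: Sequence[str], fold: int) -> None:
    present = set(train_labels)
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(
            f"fold {fold}: training remainder lacks class(es) {missing}"
        )


def loo_predictions(
    X: np.ndarray,
    y: Sequence[str],
    fit_predict: Callable[[np.ndarray, Sequence[str], np.ndarray], Sequence[str]] | None = None,
    config: SVMConfig = SVMConfig(),
) -> list[str]:
    """Leave-one-out predictions over the rows of a feature matrix.

    ``fit_predict(X_train, y_train, X_test)`` defaults to training an
    OVO RBF SVM with ``config`` and predicting the held-out row.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    if fit_predict is None:
        def fit_predict(Xtr, ytr, Xte):  # noqa: ANN001
            return train(Xtr, ytr, config).predict(Xte)

    n = X.shape[0]
    classes = list(dict.fromkeys(y))
    preds: list[str] = []
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[j] = False
        ytr = [y[i] for i in range(n) if mask[i]]
        _check_fold_classes(ytr, classes, j)
        preds.append(str(fit_predict(X[mask], ytr, X[j:j + 1])[0]))
        mask[j] = True
    return preds


def jackknife_accuracy(X, y: Sequence[str], config: SVMConfig = SVMConfig()) -> float:
    """Leave-one-out overall accuracy of the OVO RBF SVM on a matrix."""
    preds = loo_predictions(np.asarray(X, dtype=float), y, config=config)
    return float(np.mean([p == t for p, t in zip(preds, y)]))


def jackknife(
    dataset: LabeledDataset,
    tau: int | None = None,
    config: SVMConfig = SVMConfig(),
    mode: str = "paper",
    subset: Sequence[int] | None = None,
) -> tuple[list[str], ConfusionMatrix]:
    """Jackknife a labeled dataset through the full feature pipeline.

    Exactly N folds; fold j trains on every record except j and
    predicts record j. The feature subset is either given explicitly
    (``subset``), or the top-``tau`` tripeptides by confidence level:
    in "paper" mode ranked once on the full dataset, in "nested" mode
    re-ranked inside each fold on the training remainder only.
    Returns the per-record predictions (dataset order) and the
    confusion matrix.
    """
    if mode not in ("paper", "nested"):
        raise ValueError(f"mode must be 'paper' or 'nested', got {mode!r}")
    from .features import count_tripeptides

    counts = np.vstack([count_tripeptides(s)[0] for s in dataset.sequences])
    totals = counts.sum(axis=1, keepdims=True)
    comps = counts / totals
    y = list(dataset.labels)
    n = len(y)

    if subset is not None:
        cols = np.asarray(subset, dtype=np.int64)
        mode = "paper"  # explicit subset is by definition fixed in advance
    elif mode == "paper":
        if tau is None:
            raise ValueError("tau is required when no explicit subset is given")
        table = build_count_table_from_counts(counts, y, dataset.classes)
        cols = feature_subset(confidence_levels(table), tau)
    else:
        if tau is None:
            raise ValueError("tau is required in nested mode")
        cols = None  # recomputed per fold

    preds: list[str] = []
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[j] = False
        ytr = [y[i] for i in range(n) if mask[i]]
        _check_fold_classes(ytr, dataset.classes, j)
        if cols is None:
            fold_table = build_count_table_from_counts(
                counts[mask], ytr, None
            )
            fold_cols = feature_subset(confidence_levels(fold_table), tau)
        else:
            fold_cols = cols
        model = train(comps[mask][:, fold_cols], ytr, config)
        preds.append(model.predict(comps[j:j + 1, fold_cols])[0])
        mask[j] = True

    confusion = ConfusionMatrix.from_predictions(y, preds, dataset.classes)
    return preds, confusion


def export_metrics_report(report: MetricsReport, dest: str | Path) -> None:
    """TSV export: per-class counts and metrics plus an overall line."""
    lines = ["class\tTP\tTN\tFP\tFN\tSn\tSp\tMCC\n"]
    for _, row in report.per_class.iterrows():
        lines.append(
            f"{row['class']}\t{row.TP}\t{row.TN}\t{row.FP}\t{row.FN}\t"
            f"{row.Sn:.4f}\t{row.Sp:.4f}\t{row.MCC:.4f}\n"
        )
    lines.append(f"# OA\t{report.overall_accuracy:.4f}\tN\t{report.n}\n")
    lines.append(f"# macro_Sn\t{report.macro_sn:.4f}\tmacro_Sp\t{report.macro_sp:.4f}\n")
    Path(dest).write_text("".join(lines))
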