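"""End-to-end estimator: sequences in, subfamily labels out.

:class:`OTCClassifier` composes the pipeline stages — tripeptide
counting, binomial confidence-level ranking, prefix selection (fixed
tau or an IFS sweep) and the one-vs-one RBF SVM — behind the standard
scikit-learn fit/predict interface, so it drops into sklearn model
selection utilities with raw sequence strings as X.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import jackknife_accuracy
from .features import count_tripeptides
from .selection import (
    build_count_table_from_counts,
    confidence_levels,
    default_taus,
    feature_subset,
    incremental_feature_selection,
)
from .svm import SVMConfig, TrainedModel, train


class OTCClassifier(ClassifierMixin, BaseEstimator):
    """Subfamily classifier on an optimized tripeptide composition.

    Parameters
    ----------
    tau : int or "ifs", default 100
        Number of top-ranked tripeptides to keep. ``"ifs"`` sweeps the
        prefix sizes in ``taus`` with a jackknife evaluation at the
        fixed (c, gamma) and keeps the accuracy-maximising prefix.
    c, gamma : float
        SVM regularization and RBF width (midpoint-exponent defaults).
    taus : sequence of int, optional
        IFS grid; defaults to :func:`vkcotc.selection.default_taus`.

    Attributes
    ----------
    ranking_ : RankedFeatureList
        Confidence-level ranking fitted on the training data.
    subset_ : ndarray
        Selected feature indices, in ranking order.
    ifs_curve_ : IFSCurve
        Present only when ``tau="ifs"``.
    classes_ : ndarray
        Class labels in the order used by the underlying SVM.
    """

    def __init__(
        self,
        tau: int | str = 100,
        c: float = SVMConfig().c,
        gamma: float = SVMConfig().gamma,
        taus: Sequence[int] | None = None,
    ):
        self.tau = tau
        self.c = c
        self.gamma = gamma
        self.taus = taus

    def _encode(self, X: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        counts = np.vstack([count_tripeptides(s)[0] for s in X])
        comps = counts / counts.sum(axis=1, keepdims=True)
        return counts, comps

    def fit(self, X: Iterable[str], y: Sequence[str]) -> "OTCClassifier":
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        counts, comps = self._encode(X)
        config = SVMConfig(c=self.c, gamma=self.gamma)
        table = build_count_table_from_counts(counts, y)
        self.ranking_ = confidence_levels(table)
        if self.tau == "ifs":
            taus = list(self.taus) if self.taus is not None else default_taus()
            taus = [t for t in taus if t <= self.ranking_.n_features]

            def evaluator(subset: np.ndarray) -> float:
                return jackknife_accuracy(comps[:, subset], y, config)

            self.ifs_curve_ = incremental_feature_selection(
                self.ranking_, evaluator, taus
            )
            self.subset_ = self.ifs_curve_.optimal_subset
        else:
            self.subset_ = feature_subset(self.ranking_, int(self.tau))
        self.model_: TrainedModel = train(
            comps[:, self.subset_], y, config, feature_subset=self.subset_
        )
        self.classes_ = np.asarray(self.model_.classes, dtype=object)
        return self

    def predict(self, X: Iterable[str]) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = list(X)
        if not X:
            return np.empty(0, dtype=object)
        _, comps = self._encode(X)
        return np.asarray(self.model_.predict(comps[:, self.subset_]), dtype=object)
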