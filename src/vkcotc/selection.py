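"""Binomial confidence-level feature ranking and incremental feature selection.

The discriminative value of a tripeptide is scored against a null model
in which its occurrences fall into classes at random. Pool the raw
window counts of the whole dataset: if class k contributes M_k of the M
total windows, a random occurrence lands in class k with prior
probability p_k = M_k / M. For tripeptide i with N_i total occurrences,
n_ik of them in class k, the binomial tail

    P_ik = sum_{m = n_ik}^{N_i} C(N_i, m) p_k^m (1 - p_k)^(N_i - m)

is the probability of seeing a concentration at least that extreme by
chance. The confidence level CL_ik = 1 - P_ik is high exactly when the
tripeptide is non-randomly enriched in class k, and a tripeptide's
overall score is CL_i = max_k CL_ik. Ranking all 8000 tripeptides by
CL_i descending and sweeping nested prefixes S_tau of the ranking
(incremental feature selection, IFS) locates the prefix size Theta that
maximises cross-validated overall accuracy.

Ties in CL_i are common at both ends of the scale (never-observed
tripeptides all have CL = 0; strongly planted ones saturate at CL = 1
in double precision), so the ordering is made deterministic: smaller
min_k P_ik first (resolved in the tail domain, where precision near
CL = 1 survives), then smaller feature index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import binom
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import N_FEATURES, count_tripeptides, index_to_tripeptide
from .io import LabeledDataset


@dataclass
class TripeptideCountTable:
    """Pooled tripeptide occurrence counts per class.

    ``n[i, k]`` is the number of windows equal to tripeptide i summed
    over all sequences of class k. Marginals: ``N_i`` per-tripeptide row
    sums, ``M_k`` per-class column sums, ``M`` grand total.
    """

    n: np.ndarray  # (8000, K) int64
    classes: list[str]

    @property
    def N_i(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def M_k(self) -> np.ndarray:
        return self.n.sum(axis=0)

    @property
    def M(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class PriorVector:
    """Per-class prior occupancy p_k = M_k / M and its complement q_k."""

    p: np.ndarray
    q: np.ndarray


@dataclass
class RankedFeatureList:
    """Tripeptides ordered by confidence level.

    ``order`` is a permutation of [0, 8000): ``order[0]`` is the
    top-ranked feature index. ``cl`` and ``cl_detail`` give CL_i and
    CL_ik on the original (unranked) index axis; ``best_class`` holds
    the argmax class per tripeptide.
    """

    order: np.ndarray
    cl: np.ndarray
    cl_detail: np.ndarray
    best_class: np.ndarray
    classes: list[str]

    @property
    def n_features(self) -> int:
        return self.order.size


@dataclass(frozen=True)
class IFSPoint:
    tau: int
    cl_threshold: float
    overall_accuracy: float


@dataclass
class IFSCurve:
    """The accuracy-versus-prefix-size curve and its argmax Theta."""

    points: list[IFSPoint]
    theta: int
    optimal_subset: np.ndarray

    @property
    def peak_accuracy(self) -> float:
        return max(p.overall_accuracy for p in self.points)


def build_count_table(dataset: LabeledDataset) -> TripeptideCountTable:
    """Pool raw tripeptide window counts per class over a labeled dataset."""
    if len(dataset.classes) < 2:
        raise ValueError("count table needs at least 2 classes")
    return build_count_table_from_counts(
        np.vstack([count_tripeptides(s)[0] for s in dataset.sequences]),
        dataset.labels,
        dataset.classes,
    )


def build_count_table_from_counts(
    counts: np.ndarray, labels: Sequence[str], classes: Sequence[str] | None = None
) -> TripeptideCountTable:
    """Pool per-sequence count rows (n_sequences x 8000) by class label."""
    labels = list(labels)
    if classes is None:
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(lab)
        classes = list(seen)
    classes = list(classes)
    counts = np.asarray(counts)
    if counts.shape[0] != len(labels):
        raise ValueError("one label per count row required")
    n = np.zeros((counts.shape[1], len(classes)), dtype=np.int64)
    label_arr = np.asarray(labels, dtype=object)
    for k, cls in enumerate(classes):
        mask = label_arr == cls
        if not mask.any():
            raise ValueError(f"class {cls!r} has no sequences")
        n[:, k] = counts[mask].sum(axis=0)
    return TripeptideCountTable(n=n, classes=classes)


def priors(table: TripeptideCountTable) -> PriorVector:
    """Prior occupancy of each class: its share of all pooled windows."""
    M = table.M
    if M == 0:
        raise ValueError("count table is empty (no tripeptide occurrences)")
    p = table.M_k / M
    return PriorVector(p=p, q=1.0 - p)


def binomial_tail(N: int, n: int, p: float) -> float:
    """Upper binomial tail P(X >= n) for X ~ Binomial(N, p).

    Computed with the survival function, which is numerically stable for
    totals up to millions of windows; ``n = 0`` returns exactly 1.
    """
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n == 0:
        return 1.0
    return float(binom.sf(n - 1, N, p))


def confidence_levels(
    table: TripeptideCountTable, prior: PriorVector | None = None
) -> RankedFeatureList:
    """Score and rank all tripeptides by binomial confidence level.

    CL_ik = 1 - P_ik with P_ik the upper tail of Binomial(N_i, p_k) at
    n_ik; CL_i = max_k CL_ik. Never-observed tripeptides (N_i = 0) get
    CL_i = 0 and sink to the bottom of the ranking.
    """
    if prior is None:
        prior = priors(table)
    if prior.p.size != len(table.classes):
        raise ValueError("prior and count table disagree on the number of classes")
    N_i = table.N_i[:, None]
    # sf(n-1) = P(X >= n); n = 0 gives sf(-1) = 1 exactly.
    P = binom.sf(table.n - 1, N_i, prior.p[None, :])
    P = np.clip(P, 0.0, 1.0)
    cl_detail = 1.0 - P
    minP = P.min(axis=1)
    cl = 1.0 - minP
    best_class = P.argmin(axis=1)
    # Primary: CL descending. Ties broken by smaller min_k P_ik (precise
    # near CL = 1), then smaller index; lexsort keys run last-to-first.
    order = np.lexsort((np.arange(P.shape[0]), minP, -cl))
    return RankedFeatureList(
        order=order,
        cl=cl,
        cl_detail=cl_detail,
        best_class=best_class,
        classes=list(table.classes),
    )


def feature_subset(ranked: RankedFeatureList, tau: int) -> np.ndarray:
    """The first tau entries of the ranking (prefix subsets are nested)."""
    if not 1 <= tau <= ranked.n_features:
        raise ValueError(f"tau must lie in [1, {ranked.n_features}], got {tau}")
    return ranked.order[:tau].copy()


def default_taus(n_features: int = N_FEATURES) -> list[int]:
    """Default IFS grid: every size up to 1000, then stride 10.

    The full protocol evaluates every prefix 1..8000; this grid keeps
    single-feature resolution where the optimum typically falls while
    bounding the number of cross-validation runs.
    """
    taus = list(range(1, min(1000, n_features) + 1))
    taus += list(range(1010, n_features + 1, 10))
    return [t for t in taus if t <= n_features]


class IFSEvaluationError(RuntimeError):
    """Evaluator failure during the IFS sweep, annotated with the prefix size."""

    def __init__(self, tau: int, cause: Exception):
        super().__init__(f"IFS evaluator failed at tau={tau}: {cause}")
        self.tau = tau


def incremental_feature_selection(
    ranked: RankedFeatureList,
    evaluator: Callable[[np.ndarray], float],
    taus: Sequence[int],
) -> IFSCurve:
    """Sweep nested ranking prefixes and locate the accuracy peak.

    ``evaluator`` maps an ordered feature-index subset to an overall
    accuracy (typically jackknife accuracy of the downstream
    classifier). Theta is the tau of maximum accuracy; ties resolve to
    the smallest tau.
    """
    taus = list(taus)
    if not taus:
        raise ValueError("taus must be non-empty")
    if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
        raise ValueError("taus must be strictly increasing")
    if taus[0] < 1 or taus[-1] > ranked.n_features:
        raise ValueError(f"taus must lie within [1, {ranked.n_features}]")
    points: list[IFSPoint] = []
    for tau in taus:
        subset = feature_subset(ranked, tau)
        try:
            acc = float(evaluator(subset))
        except Exception as exc:  # surface the offending prefix size
            raise IFSEvaluationError(tau, exc) from exc
        cl_threshold = float(ranked.cl[ranked.order[tau - 1]])
        points.append(IFSPoint(tau=tau, cl_threshold=cl_threshold, overall_accuracy=acc))
    accs = np.array([p.overall_accuracy for p in points])
    best = int(np.argmax(accs))  # first maximum == smallest tau on ties
    theta = points[best].tau
    return IFSCurve(points=points, theta=theta, optimal_subset=feature_subset(ranked, theta))


class ConfidenceLevelSelector(TransformerMixin, BaseEstimator):
    """scikit-learn column selector driven by the binomial CL ranking.

    Fit on a raw tripeptide *count* matrix (rows are sequences, columns
    the 8000 tripeptides) with class labels; transform keeps the top
    ``tau`` ranked columns, in ranking order, of any matrix with 8000
    columns (counts or frequencies).

    Attributes
    ----------
    ranking_ : RankedFeatureList
        The full ranking with CL detail.
    subset_ : ndarray
        The selected feature indices, in ranking order.
    """

    def __init__(self, tau: int = 100):
        self.tau = tau

    def fit(self, X, y) -> "ConfidenceLevelSelector":
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D count matrix")
        table = build_count_table_from_counts(X, list(y))
        self.n_features_in_ = X.shape[1]
        self.classes_ = list(table.classes)
        self.ranking_ = confidence_levels(table)
        self.subset_ = feature_subset(self.ranking_, self.tau)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "subset_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        return X[:, self.subset_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "subset_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.subset_] = True
        return mask


def export_ranked_features(ranked: RankedFeatureList, dest: str | Path) -> None:
    """TSV export: rank, tripeptide, CL_i, best class, per-class CL_ik."""
    import pandas as pd

    rows = []
    for rank_pos, i in enumerate(ranked.order, start=1):
        row = {
            "rank": rank_pos,
            "tripeptide": index_to_tripeptide(int(i)),
            "CL": ranked.cl[i],
            "best_class": ranked.classes[int(ranked.best_class[i])],
        }
        for k, cls in enumerate(ranked.classes):
            row[f"CL_{cls}"] = ranked.cl_detail[i, k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)


def export_ifs_curve(curve: IFSCurve, dest: str | Path) -> None:
    """TSV export of (tau, cl_threshold, overall_accuracy) points."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "tau": p.tau,
                "cl_threshold": p.cl_threshold,
                "overall_accuracy": p.overall_accuracy,
            }
            for p in curve.points
        ]
    ).to_csv(dest, sep="\t", index=False)
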