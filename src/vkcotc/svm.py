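"""RBF-kernel support-vector classification with one-vs-one decomposition.

The kernel machine itself is libsvm (via scikit-learn's SVC), which
trains one binary classifier per class pair and predicts by majority
vote; voting ties resolve to the earlier class in the model's class
order. This module owns the protocol around the optimizer: the fixed
(c, gamma) defaults, the exponential grid search with its deterministic
tie rule, and model persistence with an auditable sidecar.

Tripeptide compositions of realistic-length proteins are tiny (each
frequency is on the order of 1/L), so squared distances between
composition vectors sit far below the reciprocal of every kernel width
in the searched gamma range and the raw RBF kernel is numerically
constant. Following standard kernel-machine practice, features are
therefore z-scored on the training set inside :func:`train`; the fitted
scaler travels with the model so prediction sees the same transform.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import index_to_tripeptide

#: Midpoint-exponent defaults used while tracing IFS curves, where a
#: full grid search at every prefix size would be prohibitive.
DEFAULT_C = 2.0 ** 0
DEFAULT_GAMMA = 2.0 ** -10


@dataclass(frozen=True)
class SVMConfig:
    """Regularization c and RBF width gamma; multiclass mode is fixed OVO."""

    c: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    multiclass: str = "one-vs-one"

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError(f"c and gamma must be positive, got c={self.c}, gamma={self.gamma}")
        if self.multiclass != "one-vs-one":
            raise ValueError("only one-vs-one multiclass decomposition is supported")


@dataclass(frozen=True)
class GridSpec:
    """Search grid: c = 2^e for e in -5..15, gamma = 2^e for e in -15..-5."""

    c_values: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16))
    gamma_values: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, -4))

    def __post_init__(self) -> None:
        if not self.c_values or not self.gamma_values:
            raise ValueError("grid must be non-empty")
        if any(v <= 0 for v in self.c_values) or any(v <= 0 for v in self.gamma_values):
            raise ValueError("grid values must be positive")


@dataclass
class TrainedModel:
    """A fitted OVO RBF SVM plus the feature subset it consumes.

    ``predict`` only accepts matrices whose width equals the fitted
    feature subset; the underlying estimator state is opaque.
    """

    config: SVMConfig
    feature_subset: np.ndarray
    classes: list[str]
    _svc: SVC = field(repr=False)
    _scaler: StandardScaler = field(repr=False)
    training_checksum: str = ""

    def predict(self, vectors) -> list[str]:
        vectors = np.asarray(vectors, dtype=float)
        if vectors.size == 0:
            return []
        if vectors.ndim == 1:
            vectors = vectors[None, :]
        if vectors.shape[1] != self.feature_subset.size:
            raise ValueError(
                f"probe has {vectors.shape[1]} features, model expects "
                f"{self.feature_subset.size}"
            )
        return [str(lab) for lab in self._svc.predict(self._scaler.transform(vectors))]


def _checksum(matrix: np.ndarray, labels: Sequence[str]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix, dtype=float).tobytes())
    h.update("\x1f".join(map(str, labels)).encode())
    return h.hexdigest()[:16]


def train(matrix, labels: Sequence[str], config: SVMConfig = SVMConfig(),
          feature_subset: Sequence[int] | None = None) -> TrainedModel:
    """Fit an OVO RBF-kernel SVM; deterministic for identical inputs.

    ``feature_subset`` records which tripeptide indices the columns of
    ``matrix`` correspond to (defaults to 0..width-1).
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = list(labels)
    if matrix.ndim != 2 or matrix.shape[0] != len(labels):
        raise ValueError("matrix rows and labels must align")
    if not np.isfinite(matrix).all():
        raise ValueError("feature matrix contains non-finite values")
    if len(set(labels)) < 2:
        raise ValueError("training requires at least 2 distinct classes")
    subset = (
        np.arange(matrix.shape[1], dtype=np.int64)
        if feature_subset is None
        else np.asarray(feature_subset, dtype=np.int64)
    )
    if subset.size != matrix.shape[1]:
        raise ValueError("feature_subset length must match matrix width")
    scaler = StandardScaler().fit(matrix)
    svc = SVC(C=config.c, gamma=config.gamma, kernel="rbf")
    svc.fit(scaler.transform(matrix), labels)
    return TrainedModel(
        config=config,
        feature_subset=subset,
        classes=[str(c) for c in svc.classes_],
        _svc=svc,
        _scaler=scaler,
        training_checksum=_checksum(matrix, labels),
    )


def predict(model: TrainedModel, vectors) -> list[str]:
    """One label per probe vector (thin wrapper over the model method)."""
    return model.predict(vectors)


def grid_search(
    matrix,
    labels: Sequence[str],
    grid: GridSpec = GridSpec(),
    evaluator: Callable[[np.ndarray, Sequence[str], SVMConfig], float] | None = None,
) -> tuple[SVMConfig, pd.DataFrame]:
    """Evaluate every (c, gamma) pair with a cross-validation protocol.

    ``evaluator(matrix, labels, config)`` returns an overall accuracy;
    the default is jackknife (leave-one-out) accuracy. The best pair has
    maximum accuracy, ties resolved to smaller gamma then smaller c. The
    full table of results is returned for audit.
    """
    if evaluator is None:
        from .evaluation import jackknife_accuracy

        evaluator = jackknife_accuracy
    matrix = np.asarray(matrix, dtype=float)
    rows = []
    best: tuple[float, float, float] | None = None  # (-acc, gamma, c)
    best_config = None
    for c in grid.c_values:
        for gamma in grid.gamma_values:
            config = SVMConfig(c=c, gamma=gamma)
            acc = float(evaluator(matrix, labels, config))
            rows.append({"c": c, "gamma": gamma, "accuracy": acc})
            key = (-acc, gamma, c)
            if best is None or key < best:
                best = key
                best_config = config
    table = pd.DataFrame(rows)
    assert best_config is not None
    return best_config, table


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model plus a JSON sidecar listing config, features, classes."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    sidecar = {
        "config": {"c": model.config.c, "gamma": model.config.gamma,
                   "multiclass": model.config.multiclass},
        "feature_subset": [index_to_tripeptide(int(i)) for i in model.feature_subset],
        "classes": model.classes,
        "training_checksum": model.training_checksum,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    """Load a model persisted by :func:`save_model`."""
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} does not contain a trained model")
    return model
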