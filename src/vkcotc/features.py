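"""Tripeptide-composition encoding of protein sequences.

A protein of length L contains L-2 overlapping windows of three
residues. Over the 20-letter alphabet there are 20**3 = 8000 distinct
tripeptides, so each sequence maps to an 8000-dimensional frequency
vector f_i = n_i / (L - 2), where n_i counts windows equal to the i-th
tripeptide. The mapping from tripeptides to feature indices is the
lexicographic bijection over the alphabetically ordered alphabet
("AAA" -> 0, ..., "YYY" -> 7999); the encoding is deterministic and the
frequencies sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AMINO_ACIDS, LabeledDataset

#: Number of distinct tripeptides over the 20-letter alphabet.
N_FEATURES = 20 ** 3

_AA_RANK = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
# Sparse lookup table: ASCII code -> residue rank, -1 for non-residues.
_RANK_TABLE = np.full(128, -1, dtype=np.int64)
for _aa, _r in _AA_RANK.items():
    _RANK_TABLE[ord(_aa)] = _r


def tripeptide_index(tripeptide: str) -> int:
    """Lexicographic index of a 3-residue string, in [0, 8000)."""
    if len(tripeptide) != 3:
        raise ValueError(f"expected a 3-residue string, got {tripeptide!r}")
    idx = 0
    for pos, ch in enumerate(tripeptide, start=1):
        rank = _AA_RANK.get(ch)
        if rank is None:
            raise ValueError(
                f"residue {ch!r} at position {pos} is not in the 20-letter alphabet"
            )
        idx = idx * 20 + rank
    return idx


def index_to_tripeptide(index: int) -> str:
    """Inverse of :func:`tripeptide_index`."""
    if not 0 <= index < N_FEATURES:
        raise ValueError(f"index {index} outside [0, {N_FEATURES})")
    r1, rest = divmod(index, 400)
    r2, r3 = divmod(rest, 20)
    return AMINO_ACIDS[r1] + AMINO_ACIDS[r2] + AMINO_ACIDS[r3]


def all_tripeptides() -> list[str]:
    """All 8000 tripeptides in index order."""
    return [index_to_tripeptide(i) for i in range(N_FEATURES)]


@dataclass(frozen=True)
class CompositionVector:
    """Tripeptide frequencies of one sequence plus its length."""

    values: np.ndarray
    source_length: int


def _sequence_ranks(sequence: str) -> np.ndarray:
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    ranks = _RANK_TABLE[codes]
    bad = np.nonzero(ranks < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"residue {sequence[pos]!r} at position {pos + 1} is not in the "
            "20-letter alphabet"
        )
    return ranks


def count_tripeptides(sequence: str) -> tuple[np.ndarray, int]:
    """Occurrence counts of all 8000 tripeptides (overlapping windows).

    Returns ``(counts, total)`` with ``total == len(sequence) - 2``.
    Sequences shorter than 3 residues cannot be encoded and are an error.
    """
    L = len(sequence)
    if L < 3:
        raise ValueError(f"sequence of length {L} is too short to encode (need >= 3)")
    ranks = _sequence_ranks(sequence)
    idx = 400 * ranks[:-2] + 20 * ranks[1:-1] + ranks[2:]
    counts = np.bincount(idx, minlength=N_FEATURES).astype(np.int64)
    return counts, L - 2


def composition(sequence: str) -> CompositionVector:
    """Tripeptide composition f_i = n_i / (L - 2) of one sequence."""
    counts, total = count_tripeptides(sequence)
    return CompositionVector(values=counts / total, source_length=len(sequence))


def _validate_subset(subset: Sequence[int]) -> np.ndarray:
    arr = np.asarray(subset, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("feature subset must be a non-empty 1-D index sequence")
    if arr.min() < 0 or arr.max() >= N_FEATURES:
        raise ValueError(f"feature subset indices must lie in [0, {N_FEATURES})")
    if np.unique(arr).size != arr.size:
        raise ValueError("feature subset contains duplicate indices")
    return arr


def encode_sequences(
    sequences: Iterable[str],
    subset: Sequence[int] | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Encode sequences as a (n_sequences, n_features) matrix.

    Without ``subset`` columns span all 8000 features in index order;
    with it, columns follow the subset order exactly. ``normalize=False``
    returns raw window counts instead of frequencies.
    """
    cols = _validate_subset(subset) if subset is not None else None
    rows = []
    for seq in sequences:
        counts, total = count_tripeptides(seq)
        vec = counts / total if normalize else counts.astype(float)
        rows.append(vec if cols is None else vec[cols])
    width = N_FEATURES if cols is None else cols.size
    if not rows:
        return np.empty((0, width))
    return np.vstack(rows)


def encode_dataset(
    dataset: LabeledDataset,
    subset: Sequence[int] | None = None,
    normalize: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Encode a labeled dataset; rows follow dataset order."""
    matrix = encode_sequences(dataset.sequences, subset=subset, normalize=normalize)
    return matrix, list(dataset.labels)


class TripeptideEncoder(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn transformer from sequences to tripeptide space.

    Parameters
    ----------
    subset : sequence of int, optional
        Feature indices to keep, in the given order. ``None`` keeps all
        8000 features in index order.
    normalize : bool, default True
        Emit frequencies (counts divided by L - 2) rather than raw counts.
    """

    def __init__(self, subset: Sequence[int] | None = None, normalize: bool = True):
        self.subset = subset
        self.normalize = normalize

    def fit(self, X: Iterable[str], y=None) -> "TripeptideEncoder":
        if self.subset is not None:
            _validate_subset(self.subset)
        self.n_features_in_ = 1  # one sequence string per sample
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        return encode_sequences(X, subset=self.subset, normalize=self.normalize)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        idx = range(N_FEATURES) if self.subset is None else self.subset
        return np.asarray([index_to_tripeptide(int(i)) for i in idx], dtype=object)


def write_feature_matrix(
    matrix: np.ndarray,
    record_ids: Sequence[str],
    labels: Sequence[str] | None,
    dest: str | Path,
    feature_indices: Sequence[int] | None = None,
) -> None:
    """Export a feature matrix as TSV with tripeptide-string column names."""
    import pandas as pd

    idx = feature_indices if feature_indices is not None else range(matrix.shape[1])
    columns = [index_to_tripeptide(int(i)) for i in idx]
    df = pd.DataFrame(matrix, index=list(record_ids), columns=columns)
    df.index.name = "record_id"
    if labels is not None:
        df.insert(0, "label", list(labels))
    df.to_csv(dest, sep="\t")


def read_feature_subset(source: str | Path) -> list[int]:
    """Read a feature-subset file: one tripeptide or integer index per line."""
    indices: list[int] = []
    for line in Path(source).read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token.isdigit():
            indices.append(int(token))
        else:
            indices.append(tripeptide_index(token.upper()))
    _validate_subset(indices)
    return indices


def write_feature_subset(indices: Sequence[int], dest: str | Path) -> None:
    """Write a feature subset as one tripeptide string per line."""
    Path(dest).write_text(
        "".join(index_to_tripeptide(int(i)) + "\n" for i in indices)
    )
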