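"""Deterministic k-nearest-neighbour classification on a feature subset.

This is the base-classifier engine of the Random KNN ensemble: queries are
classified against a base set by Euclidean distance restricted to a random
subspace's columns.  Everything here is deliberately deterministic —
distance ties at the k-th neighbour are broken by a row-order-independent
key, and vote ties by the canonical (sorted) label order — so that
identical inputs always give identical predictions, a precondition for
reproducible feature supports downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ParameterError

__all__ = ["FeatureSubset", "knn_classify", "majority_vote"]


@dataclass(frozen=True)
class FeatureSubset:
    """A set of distinct feature column positions, canonically sorted."""

    indices: tuple[int, ...]

    def __init__(self, indices: Sequence[int]) -> None:
        idx = tuple(sorted(int(j) for j in indices))
        if len(idx) == 0:
            raise ParameterError("feature subset must be non-empty")
        if len(set(idx)) != len(idx):
            raise ParameterError("feature subset indices must be distinct")
        if idx[0] < 0:
            raise ParameterError("feature subset indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=np.intp)

    def validate_for(self, p: int) -> None:
        if self.indices[-1] >= p:
            raise ParameterError(
                f"feature index {self.indices[-1]} out of range for p={p}"
            )


def majority_vote(labels: Sequence[str]) -> str:
    """Most frequent label; ties go to the first label in sorted order."""
    labels = list(labels)
    if not labels:
        raise ParameterError("majority_vote requires a non-empty label sequence")
    classes = sorted(set(labels))
    counts = [0] * len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    for lab in labels:
        counts[pos[lab]] += 1
    # max() keeps the earliest (canonically smallest) label on count ties
    return classes[int(np.argmax(counts))]


def _vote_codes(
    base_sub: np.ndarray,
    base_codes: np.ndarray,
    query_sub: np.ndarray,
    k: int,
    n_classes: int,
    order_key: np.ndarray,
) -> np.ndarray:
    """Predicted class codes for each query row (internal fast path).

    ``base_sub`` / ``query_sub`` are already restricted to the subspace's
    columns; ``base_codes`` are integer labels under the canonical order and
    ``order_key`` is the row-order-independent tie-break key (rank of the
    base sample's identifier).
    """
    # Pre-sorting base rows by the tie-break key makes a stable distance
    # sort resolve exact-distance ties by that key, independent of row order.
    perm = np.argsort(order_key, kind="stable")
    d2 = cdist(query_sub, base_sub[perm], metric="sqeuclidean")
    if k < d2.shape[1]:
        part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        rows = np.arange(d2.shape[0])[:, None]
        # stable ordering inside the k-block keeps determinism on ties that
        # straddle the partition boundary
        fine = np.argsort(d2[rows, part], axis=1, kind="stable")
        nearest = part[rows, fine]
        # argpartition may split a tie group arbitrarily at position k-1;
        # redo exactly when the boundary is ambiguous
        kth = d2[rows, nearest[:, -1:]]
        ambiguous = (d2 <= kth).sum(axis=1) > k
        if np.any(ambiguous):
            full = np.argsort(d2[ambiguous], axis=1, kind="stable")[:, :k]
            nearest[ambiguous] = full
    else:
        nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = base_codes[perm][nearest]
    counts = np.zeros((query_sub.shape[0], n_classes), dtype=np.int64)
    rows = np.repeat(np.arange(query_sub.shape[0]), k)
    np.add.at(counts, (rows, votes.ravel()), 1)
    return counts.argmax(axis=1)  # earliest class code wins ties


def knn_classify(
    base_X: np.ndarray,
    base_y: Sequence[str],
    query_X: np.ndarray,
    k: int,
    subset: FeatureSubset,
    base_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Classify each query row by the majority label of its ``k`` nearest
    base rows, with distances computed only over ``subset``'s columns.

    Parameters
    ----------
    base_X, base_y
        Reference points and their labels.
    query_X
        Points to classify; must have the same number of columns as
        ``base_X``.
    k
        Neighbour count; must not exceed the number of base rows.
    subset
        Feature columns over which Euclidean distance is computed.
    base_ids
        Optional orderable identifiers for the base rows.  Exact distance
        ties at the k-th neighbour are broken by this key so the selected
        neighbour set does not depend on row order; defaults to row index.

    Returns
    -------
    numpy.ndarray of object
        One predicted label per query row.
    """
    base_X = np.asarray(base_X, dtype=np.float64)
    query_X = np.asarray(query_X, dtype=np.float64)
    if base_X.ndim != 2 or query_X.ndim != 2:
        raise ParameterError("base_X and query_X must be 2-dimensional")
    if base_X.shape[1] != query_X.shape[1]:
        raise ParameterError(
            f"base has {base_X.shape[1]} columns but query has {query_X.shape[1]}"
        )
    if k < 1:
        raise ParameterError(f"k must be positive, got {k}")
    if k > base_X.shape[0]:
        raise ParameterError(
            f"k={k} exceeds the number of base samples ({base_X.shape[0]})"
        )
    subset.validate_for(base_X.shape[1])
    y = np.asarray([str(v) for v in base_y], dtype=object)
    if len(y) != base_X.shape[0]:
        raise ParameterError("base_y length must match base_X rows")
    classes = np.asarray(sorted(set(y)), dtype=object)
    codes = np.searchsorted(classes, y).astype(np.intp)
    if base_ids is None:
        order_key = np.arange(base_X.shape[0])
    else:
        ids = list(base_ids)
        if len(ids) != base_X.shape[0]:
            raise ParameterError("base_ids length must match base_X rows")
        order_key = np.argsort(np.argsort(np.asarray(ids, dtype=object), kind="stable"))
    cols = subset.as_array()
    pred = _vote_codes(
        np.ascontiguousarray(base_X[:, cols]),
        codes,
        np.ascontiguousarray(query_X[:, cols]),
        k,
        len(classes),
        order_key,
    )
    return classes[pred]
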