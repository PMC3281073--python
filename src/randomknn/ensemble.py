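"""The Random KNN classifier: r base KNNs on random m-feature subspaces.

Each base classifier sees only a random subspace of m features drawn with
equiprobability (without replacement within a subspace, independently
across subspaces).  A query is classified by every base KNN, and the final
label is the majority over the r base votes — "a majority of a majority".
Because KNN itself is a stable learner, the ensemble does not bootstrap
samples; diversity comes entirely from the feature subspaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset, RknnParams
from .exceptions import DataError, ParameterError
from .knn_core import FeatureSubset, _vote_codes

__all__ = ["RknnModel", "draw_feature_subsets", "fit_rknn", "rknn_predict"]


def draw_feature_subsets(
    p: int,
    m: int,
    r: int,
    rng: np.random.Generator,
) -> list[FeatureSubset]:
    """Draw ``r`` independent uniform random m-subsets of ``{0, ..., p-1}``.

    Indices within a subset are distinct (sampling without replacement);
    the same subset may recur across draws.  Reproducible from ``rng``.
    """
    if not (1 <= m <= p):
        raise ParameterError(f"m must satisfy 1 <= m <= p, got m={m}, p={p}")
    if r < 1:
        raise ParameterError(f"r must be positive, got {r}")
    return [FeatureSubset(rng.choice(p, size=m, replace=False)) for _ in range(r)]


@dataclass(frozen=True)
class RknnModel:
    """A fitted Random KNN classifier.

    Holds the training data, the resolved parameters, and the r feature
    subspaces.  Prediction uses the *entire* training set as the base for
    every base KNN; base/query partitioning exists only inside support
    computation, where per-classifier accuracies must be measured.
    """

    training: Dataset
    params: RknnParams
    subsets: tuple[FeatureSubset, ...]

    def __post_init__(self) -> None:
        m = self.params.resolve_m(self.training.n_features)
        for s in self.subsets:
            s.validate_for(self.training.n_features)
            if len(s) != m:
                raise ParameterError(
                    f"every subset must have size m={m}, found size {len(s)}"
                )

    @property
    def r(self) -> int:
        return len(self.subsets)

    def predict(self, query_X: np.ndarray) -> np.ndarray:
        return rknn_predict(self, query_X)


def fit_rknn(dataset: Dataset, params: RknnParams) -> RknnModel:
    """Build a Random KNN model: draw r subspaces of size m from the seed."""
    if params.k > dataset.n_samples:
        raise ParameterError(
            f"k={params.k} exceeds the number of training samples ({dataset.n_samples})"
        )
    # any standardisation (params.zscore) is applied by the calling
    # workflow so that queries receive the identical transform
    m = params.resolve_m(dataset.n_features)
    rng = np.random.default_rng(params.seed)
    subsets = draw_feature_subsets(dataset.n_features, m, params.r, rng)
    return RknnModel(training=dataset, params=params, subsets=tuple(subsets))


def rknn_predict(model: RknnModel, query_X: np.ndarray) -> np.ndarray:
    """Majority-of-a-majority prediction for each query row.

    Every base KNN votes via its own subspace (full training set as base);
    the final label is the majority of the r base votes, ties broken by
    canonical label order.
    """
    train = model.training
    query_X = np.atleast_2d(np.asarray(query_X, dtype=np.float64))
    if query_X.shape[1] != train.n_features:
        raise DataError(
            f"query has {query_X.shape[1]} columns but the model was trained "
            f"on {train.n_features} features"
        )
    classes = np.asarray(train.classes, dtype=object)
    codes = train.label_codes()
    # sample ids give the row-order-independent neighbour tie-break
    order_key = np.argsort(
        np.argsort(np.asarray(train.sample_ids, dtype=object), kind="stable")
    )
    counts = np.zeros((query_X.shape[0], len(classes)), dtype=np.int64)
    rows = np.arange(query_X.shape[0])
    X = train.X
    for subset in model.subsets:
        cols = subset.as_array()
        pred = _vote_codes(
            np.ascontiguousarray(X[:, cols]),
            codes,
            np.ascontiguousarray(query_X[:, cols]),
            model.params.k,
            len(classes),
            order_key,
        )
        counts[rows, pred] += 1
    return classes[counts.argmax(axis=1)]
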