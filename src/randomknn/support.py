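"""Feature supports by bidirectional voting.

Each feature participates in some of the r base KNN classifiers; each base
classifier's accuracy, measured by classifying a held-back query half of
the samples against a base half, is credited back to every feature in its
subspace.  A feature's *support* is the mean accuracy of the classifiers
containing it, and its *multiplicity* M(f) is how many contain it.  Votes
flow in both directions: features vote for class labels through their
classifiers, and classification accuracies vote back for features.

Bookkeeping identity (the conservation check used throughout the tests):

    sum_f M(f) * support(f) = m * sum_over_classifiers acc      and
    sum_f M(f) = r * m

since each classifier credits its accuracy to exactly m features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, RknnParams
from .ensemble import draw_feature_subsets
from .exceptions import ParameterError, StateError
from .knn_core import FeatureSubset, _vote_codes

__all__ = [
    "BaseClassifierRecord",
    "SupportRanking",
    "partition_samples",
    "compute_supports",
    "rank_features",
]


@dataclass(frozen=True)
class BaseClassifierRecord:
    """One base KNN: its subspace, its sample partition, its accuracy."""

    subset: FeatureSubset
    base_indices: tuple[int, ...]
    query_indices: tuple[int, ...]
    acc: float


@dataclass(frozen=True)
class SupportRanking:
    """Per-feature supports and multiplicities from one Random KNN run.

    ``support[j]`` is NaN where ``multiplicity[j] == 0``: a feature that no
    classifier sampled has *undefined* support and is reported as unranked,
    never imputed as zero (zero would wrongly mark it maximally irrelevant).
    ``mean_acc`` is the mean accuracy over all r base classifiers — the
    ensemble-level criterion used to compare feature sets during
    elimination.
    """

    feature_ids: tuple[str, ...]
    support: np.ndarray
    multiplicity: np.ndarray
    mean_acc: float
    r: int
    m: int

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of features with at least one containing classifier."""
        return self.multiplicity > 0

    def ranked_order(self) -> np.ndarray:
        """Feature positions sorted by (support desc, multiplicity desc,
        feature id asc); undefined-support features appended in id order."""
        n = len(self.feature_ids)
        ids = np.asarray(self.feature_ids, dtype=object)
        id_rank = np.argsort(np.argsort(ids, kind="stable"))
        support = np.where(self.defined, self.support, -np.inf)
        # lexsort: last key is primary
        order = np.lexsort((id_rank, -self.multiplicity, -support))
        return order.astype(np.intp)

    def top_features(self, n_keep: int) -> list[str]:
        order = self.ranked_order()
        return [self.feature_ids[j] for j in order[:n_keep]]

    def as_frame(self) -> pd.DataFrame:
        """Table with columns feature_id, multiplicity, support, rank."""
        order = self.ranked_order()
        rank = np.full(len(self.feature_ids), -1, dtype=int)
        pos = 1
        for j in order:
            if self.multiplicity[j] > 0:
                rank[j] = pos
                pos += 1
        df = pd.DataFrame(
            {
                "feature_id": list(self.feature_ids),
                "multiplicity": self.multiplicity,
                "support": self.support,
                "rank": [r if r > 0 else pd.NA for r in rank],
            }
        )
        return df.iloc[order].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def partition_samples(
    n: int,
    mode: str,
    rng: np.random.Generator,
    k: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split of ``{0, ..., n-1}`` into (base, query) indices.

    The base half gets the extra sample when n is odd (``ceil(n/2)``) so the
    neighbour search has the larger pool.  ``mode`` is validated here but
    the dynamic/fixed distinction is enforced by the caller: dynamic draws a
    fresh partition per base classifier, fixed reuses one draw.
    """
    if mode not in ("dynamic", "fixed"):
        raise ParameterError(f"unknown partition mode {mode!r}")
    n_base = (n + 1) // 2
    if n_base < k:
        raise ParameterError(
            f"base half ({n_base} of n={n}) is smaller than k={k}; use a smaller k"
        )
    if n - n_base < 1:
        raise ParameterError(f"n={n} leaves an empty query half")
    perm = rng.permutation(n)
    base = np.sort(perm[:n_base])
    query = np.sort(perm[n_base:])
    return base, query


def compute_supports(
    dataset: Dataset,
    params: RknnParams,
    rng: np.random.Generator | None = None,
    subsets: Sequence[FeatureSubset] | None = None,
    partitions: Sequence[tuple[Sequence[int], Sequence[int]]] | None = None,
    return_records: bool = False,
) -> SupportRanking | tuple[SupportRanking, list[BaseClassifierRecord]]:
    """Run the bidirectional-voting procedure and return feature supports.

    Builds r base KNN classifiers: each draws an m-feature subspace and a
    base/query half-split of the samples, classifies the query half against
    the base half, and records its accuracy.  Supports are the per-feature
    mean accuracies over containing classifiers.

    Parameters
    ----------
    dataset, params
        The data and the ensemble parameters (r, m, k, partition_mode, seed).
    rng
        Optional generator overriding ``params.seed`` — used by the
        elimination stages to chain one reproducible random stream.
    subsets, partitions
        Explicit subspaces / partitions overriding the random draws; for
        hand-checked calculations and fixed-design tests.  When given, their
        length defines r.
    return_records
        Also return the per-classifier records (subspace, partition,
        accuracy).
    """
    if params.zscore:
        dataset = dataset.zscore()
    n, p = dataset.n_samples, dataset.n_features
    m = params.resolve_m(p)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if subsets is None:
        r = params.r
        subsets = draw_feature_subsets(p, m, r, rng)
    else:
        subsets = list(subsets)
        r = len(subsets)
        for s in subsets:
            s.validate_for(p)
        m = len(subsets[0])
        if any(len(s) != m for s in subsets):
            raise ParameterError("all explicit subsets must share one size m")
    if partitions is not None:
        partitions = [
            (np.asarray(b, dtype=np.intp), np.asarray(q, dtype=np.intp))
            for b, q in partitions
        ]
        if len(partitions) != r:
            raise ParameterError("need one explicit partition per classifier")
    elif params.partition_mode == "fixed":
        partitions = [partition_samples(n, "fixed", rng, params.k)] * r
    else:
        partitions = None  # drawn per classifier below

    codes = dataset.label_codes()
    n_classes = dataset.n_classes
    X = dataset.X
    id_rank = np.argsort(
        np.argsort(np.asarray(dataset.sample_ids, dtype=object), kind="stable")
    )
    support_sum = np.zeros(p)
    mult = np.zeros(p, dtype=np.int64)
    accs = np.empty(r)
    records: list[BaseClassifierRecord] = []
    for i in range(r):
        if partitions is None:
            base_idx, query_idx = partition_samples(n, "dynamic", rng, params.k)
        else:
            base_idx, query_idx = partitions[i]
        cols = subsets[i].as_array()
        pred = _vote_codes(
            np.ascontiguousarray(X[np.ix_(base_idx, cols)]),
            codes[base_idx],
            np.ascontiguousarray(X[np.ix_(query_idx, cols)]),
            params.k,
            n_classes,
            id_rank[base_idx],
        )
        acc = float(np.mean(pred == codes[query_idx]))
        accs[i] = acc
        support_sum[cols] += acc
        mult[cols] += 1
        if return_records:
            records.append(
                BaseClassifierRecord(
                    subset=subsets[i],
                    base_indices=tuple(int(v) for v in base_idx),
                    query_indices=tuple(int(v) for v in query_idx),
                    acc=acc,
                )
            )
    with np.errstate(invalid="ignore"):
        support = np.where(mult > 0, support_sum / np.maximum(mult, 1), np.nan)
    ranking = SupportRanking(
        feature_ids=dataset.feature_ids,
        support=support,
        multiplicity=mult,
        mean_acc=float(accs.mean()),
        r=r,
        m=m,
    )
    if np.any(mult == 0):
        warnings.warn(
            f"{int(np.sum(mult == 0))} feature(s) were never sampled by any "
            "base classifier; their support is undefined (increase r or m)",
            stacklevel=2,
        )
    if return_records:
        return ranking, records
    return ranking


def rank_features(ranking: SupportRanking) -> list[str]:
    """Feature ids from most to least relevant.

    Defined-support features first, sorted by support descending with ties
    broken by higher multiplicity then feature id; never-sampled features
    are appended last in id order (they are unranked, see
    :meth:`SupportRanking.as_frame`).
    """
    if not np.any(ranking.defined):
        raise StateError(
            "no feature has defined support; r * m is too small to cover any feature"
        )
    return [ranking.feature_ids[j] for j in ranking.ranked_order()]
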