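"""Dataset container, parameter record, and delimited-text I/O.

The central object is :class:`Dataset`: an ``n x p`` matrix of numeric
feature values (rows are samples, columns are features, e.g. genes) plus one
categorical label per sample.  Labels are opaque strings; their canonical
sorted order is the deterministic tie-break basis used everywhere else in
the package.  Missing values are rejected outright — imputation is a
preprocessing concern that must happen before the data reach this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, ParameterError

__all__ = ["Dataset", "RknnParams", "read_dataset", "write_dataset"]

#: Header name used for the sample-identifier column on write, and
#: recognised on read.
SAMPLE_ID_COLUMN = "sample_id"


@dataclass(frozen=True)
class Dataset:
    """A labelled samples-by-features matrix.

    Parameters
    ----------
    X
        Real matrix of shape ``(n, p)``; rows are samples, columns features.
    y
        Sequence of ``n`` class labels (coerced to strings).
    feature_ids
        ``p`` unique feature identifiers.
    sample_ids
        ``n`` unique sample identifiers.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[str],
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise DataError(f"X must be 2-dimensional, got shape {X.shape}")
        n, p = X.shape
        if p == 0:
            raise DataError("dataset must have at least one feature")
        y = np.asarray([str(v) for v in y], dtype=object)
        if feature_ids is None:
            feature_ids = tuple(f"F{j + 1}" for j in range(p))
        else:
            feature_ids = tuple(str(f) for f in feature_ids)
        if sample_ids is None:
            sample_ids = tuple(f"S{i + 1}" for i in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
        if len(y) != n:
            raise DataError(f"{n} rows in X but {len(y)} labels")
        if len(sample_ids) != n:
            raise DataError(f"{n} rows in X but {len(sample_ids)} sample ids")
        if len(feature_ids) != p:
            raise DataError(f"{p} columns in X but {len(feature_ids)} feature ids")
        if len(set(feature_ids)) != p:
            raise DataError("feature ids must be unique")
        if len(set(sample_ids)) != n:
            raise DataError("sample ids must be unique")
        if not np.all(np.isfinite(X)):
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise DataError(
                f"non-finite value at sample {sample_ids[i]!r}, "
                f"feature {feature_ids[j]!r}; missing values are rejected, not imputed"
            )
        if len(np.unique(y)) < 2:
            raise DataError("dataset must contain at least 2 distinct classes")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        self.X.setflags(write=False)
        self.y.setflags(write=False)

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct labels in canonical (sorted) order."""
        return tuple(sorted(set(self.y)))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def label_codes(self) -> np.ndarray:
        """Integer codes of ``y`` under the canonical label order."""
        classes = np.asarray(self.classes, dtype=object)
        return np.searchsorted(classes, self.y).astype(np.intp)

    # ------------------------------------------------------------ subsetting
    def subset_features(self, indices: Sequence[int]) -> "Dataset":
        """New dataset restricted to the given feature columns (order kept)."""
        idx = np.asarray(indices, dtype=np.intp)
        return Dataset(
            self.X[:, idx],
            self.y,
            [self.feature_ids[j] for j in idx],
            self.sample_ids,
        )

    def subset_samples(self, indices: Sequence[int]) -> "Dataset":
        """New dataset restricted to the given sample rows (order kept)."""
        idx = np.asarray(indices, dtype=np.intp)
        return Dataset(
            self.X[idx],
            self.y[idx],
            self.feature_ids,
            [self.sample_ids[i] for i in idx],
        )

    def features_by_id(self, ids: Sequence[str]) -> "Dataset":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        try:
            idx = [pos[f] for f in ids]
        except KeyError as exc:
            raise ConfigError(f"unknown feature id {exc.args[0]!r}") from None
        return self.subset_features(idx)

    def zscore(self) -> "Dataset":
        """Per-feature standardisation (mean 0, sd 1; constant columns -> 0).

        Off by default everywhere: KNN distances are scale-sensitive, so
        rescaling must be an explicit, recorded choice.
        """
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return replace_matrix(self, (self.X - mu) / sd)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            np.array_equal(self.X, other.X)
            and np.array_equal(self.y, other.y)
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
        )


def replace_matrix(dataset: Dataset, X: np.ndarray) -> Dataset:
    """Dataset with the same labels/ids but a new matrix of equal shape."""
    return Dataset(X, dataset.y, dataset.feature_ids, dataset.sample_ids)


@dataclass(frozen=True)
class RknnParams:
    """Tunable parameters of the Random KNN ensemble and of RKNN-FS.

    Attributes
    ----------
    k
        Neighbour count of each base KNN.  Small values (1 or 3) suit the
        small-n, large-p regime.
    r
        Number of base classifiers in the ensemble.
    m
        Random-subspace size.  ``None`` (the default) means the
        ``round(sqrt(p))`` rule, re-evaluated from the current feature count
        whenever the feature set shrinks during elimination; an explicit
        integer is capped at the current ``p`` at every use site.
    q
        Proportion of features dropped per geometric-elimination iteration.
    d
        Features dropped per linear-stage iteration.
    partition_mode
        ``"dynamic"`` redraws the base/query half-split per base classifier;
        ``"fixed"`` draws it once per support computation.
    seed
        Master random seed; fixes subsets, partitions and hence every output.
    min_dim
        Floor on the retained feature count during elimination.
    zscore
        Standardise features before any distance computation.
    """

    k: int = 3
    r: int = 2000
    m: int | None = None
    q: float = 0.2
    d: int = 1
    partition_mode: str = "dynamic"
    seed: int = 0
    min_dim: int = 4
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be a positive integer, got {self.k}")
        if self.r < 1:
            raise ParameterError(f"r must be a positive integer, got {self.r}")
        if self.m is not None and self.m < 1:
            raise ParameterError(f"m must be a positive integer, got {self.m}")
        if not (0.0 < self.q < 1.0):
            raise ParameterError(f"q must lie in (0, 1), got {self.q}")
        if self.d < 1:
            raise ParameterError(f"d must be a positive integer, got {self.d}")
        if self.partition_mode not in ("dynamic", "fixed"):
            raise ParameterError(
                f"partition_mode must be 'dynamic' or 'fixed', got {self.partition_mode!r}"
            )
        if self.min_dim < 1:
            raise ParameterError(f"min_dim must be positive, got {self.min_dim}")

    def resolve_m(self, p: int) -> int:
        """Subspace size for a feature set of size ``p``."""
        if p < 1:
            raise ParameterError("p must be positive")
        if self.m is None:
            return max(1, min(p, round(math.sqrt(p))))
        return min(self.m, p)

    def with_seed(self, seed: int) -> "RknnParams":
        return replace(self, seed=int(seed))


# --------------------------------------------------------------------- I/O


def _sniff_delimiter(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return "\t" if name.endswith((".tsv", ".txt")) else ","


def read_dataset(
    path: str | Path,
    label_column: str = "label",
    delimiter: str | None = None,
) -> Dataset:
    """Read a delimited text file into a :class:`Dataset`.

    The file must have a header row and one row per sample.  The column named
    ``label_column`` holds the class labels (taken verbatim as strings); a
    column named ``sample_id``, if present, holds sample identifiers; every
    other column is a numeric feature, in file order.  Gzip compression is
    detected from the ``.gz`` extension.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise ConfigError(
            f"label column {label_column!r} not found in {path} "
            f"(columns: {', '.join(df.columns[:8])}...)"
        )
    y = df[label_column].tolist()
    if SAMPLE_ID_COLUMN in df.columns and SAMPLE_ID_COLUMN != label_column:
        sample_ids = df[SAMPLE_ID_COLUMN].tolist()
        feat = df.drop(columns=[label_column, SAMPLE_ID_COLUMN])
    else:
        sample_ids = None
        feat = df.drop(columns=[label_column])
    values = np.empty(feat.shape, dtype=np.float64)
    for j, col in enumerate(feat.columns):
        raw = feat[col].to_numpy(dtype=object)
        try:
            # numpy's str->float conversion is correctly rounded, so the
            # write/read round trip is exact; pandas' fast parser is not
            parsed = raw.astype(np.float64)
            if not np.all(np.isfinite(parsed)):
                raise ValueError
        except (ValueError, TypeError):
            coerced = pd.to_numeric(feat[col].replace("", np.nan), errors="coerce")
            bad = np.flatnonzero(~np.isfinite(coerced.to_numpy(dtype=np.float64)))
            i = int(bad[0]) if bad.size else 0
            cell = raw[i]
            what = "missing" if cell == "" else f"non-numeric ({cell!r})"
            raise DataError(
                f"{what} value at row {i + 2} (data row {i + 1}), column {col!r} of {path}"
            ) from None
        values[:, j] = parsed
    return Dataset(values, y, feature_ids=list(feat.columns), sample_ids=sample_ids)


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    delimiter: str | None = None,
    label_column: str = "label",
) -> None:
    """Write a :class:`Dataset` as delimited text; inverse of :func:`read_dataset`.

    Values are printed at full ``repr`` precision so the round trip is exact.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.DataFrame(dataset.X, columns=list(dataset.feature_ids))
    df.insert(0, SAMPLE_ID_COLUMN, list(dataset.sample_ids))
    df[label_column] = list(dataset.y)
    try:
        df.to_csv(path, sep=delimiter, index=False, float_format=None)
    except OSError as exc:
        raise ConfigError(f"cannot write dataset to {path}: {exc}") from exc
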