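"""External leave-one-out cross-validation and stability statistics.

When feature selection is part of the modelling pipeline, an honest LOOCV
must be *external*: the whole selection procedure is redone from scratch on
each set of n-1 samples, and the held-out sample only ever meets the final
fitted model.  Selecting features once on all n samples and then
cross-validating the classifier alone leaks the held-out label into the
selection and biases accuracy upward.

Stability is summarised two ways, mirroring how feature-selection methods
are compared on expression data: the standard deviation and coefficient of
variation (x100) of accuracy across repeated runs, and the mean/SD of the
selected-set size (across folds within a run, and across runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import Dataset, RknnParams
from .ensemble import rknn_predict
from .exceptions import ParameterError
from .selection import rknn_fs

__all__ = ["EvalResult", "StabilitySummary", "fold_seed", "loocv_external", "stability_summary"]


def fold_seed(master_seed: int, fold: int) -> int:
    """Per-fold seed derived from the master seed (splitmix64-style mix).

    Folds get decorrelated, reproducible random streams; the result is kept
    below 2**31.
    """
    z = (int(master_seed) + (fold + 1) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return int((z ^ (z >> 31)) % (2**31))


def _sample_sd(values: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator); 0 for a single value."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1))


@dataclass(frozen=True)
class EvalResult:
    """Outcome of one external-LOOCV run.

    ``fold_correct`` holds one boolean per evaluated fold; folds whose
    removal left the dataset with a missing class are skipped (listed in
    ``skipped_folds``) and excluded from the accuracy.  ``fold_set_sizes``
    records how many features each fold's selection retained, whose spread
    across folds is itself a stability measure.
    """

    fold_correct: tuple[bool, ...]
    loocv_accuracy: float
    fold_set_sizes: tuple[int, ...]
    set_size_mean: float
    set_size_sd: float
    skipped_folds: tuple[int, ...] = ()

    @property
    def n_folds(self) -> int:
        return len(self.fold_correct)


@dataclass(frozen=True)
class StabilitySummary:
    """Across-run stability statistics of accuracy and selected-set size."""

    n_runs: int
    accuracy_mean: float
    accuracy_sd: float
    accuracy_cv: float  # 100 * sd / mean
    set_size_mean: float
    set_size_sd: float
    note: str = ""


def loocv_external(
    dataset: Dataset,
    params: RknnParams,
    stage1_only: bool = False,
) -> EvalResult:
    """External LOOCV of RKNN-FS: selection redone inside every fold.

    For each sample i, RKNN-FS runs on the other n-1 samples (with a fold
    seed derived from ``params.seed``) and the resulting final model
    classifies sample i.  The held-out sample therefore never influences
    support computation or elimination in its own fold.
    """
    n = dataset.n_samples
    if n < 3:
        raise ParameterError(f"external LOOCV needs at least 3 samples, got n={n}")
    if params.zscore:
        # standardisation must also be internal to the fold; rknn_fs applies
        # it to the fold's training data, and the query is transformed with
        # the fold's statistics below
        pass
    y = dataset.y
    correct: list[bool] = []
    sizes: list[int] = []
    skipped: list[int] = []
    counts = {c: int(np.sum(y == c)) for c in dataset.classes}
    for i in range(n):
        if counts[y[i]] == 1:
            warnings.warn(
                f"fold {i} skipped: held-out sample {dataset.sample_ids[i]!r} "
                f"is the only member of class {y[i]!r}",
                stacklevel=2,
            )
            skipped.append(i)
            continue
        keep = [j for j in range(n) if j != i]
        fold_data = dataset.subset_samples(keep)
        fold_params = params.with_seed(fold_seed(params.seed, i))
        query = dataset.X[i : i + 1, :]
        if params.zscore:
            mu = fold_data.X.mean(axis=0)
            sd = fold_data.X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            query = (query - mu) / sd
        result = rknn_fs(fold_data, fold_params, stage1_only=stage1_only)
        cols = [dataset.feature_ids.index(f) for f in result.selected]
        pred = rknn_predict(result.model, query[:, cols])[0]
        correct.append(bool(pred == y[i]))
        sizes.append(len(result.selected))
    if not correct:
        raise ParameterError("every fold was skipped; dataset is degenerate")
    sizes_arr = np.asarray(sizes, dtype=float)
    return EvalResult(
        fold_correct=tuple(correct),
        loocv_accuracy=float(np.mean(correct)),
        fold_set_sizes=tuple(sizes),
        set_size_mean=float(sizes_arr.mean()),
        set_size_sd=_sample_sd(sizes_arr),
        skipped_folds=tuple(skipped),
    )


def stability_summary(results: list[EvalResult] | tuple[EvalResult, ...]) -> StabilitySummary:
    """Stability of accuracy and selected-set size across repeated runs.

    ``results`` are typically repeated :func:`loocv_external` runs under
    different master seeds.  Reports mean/SD/CVx100 of accuracy and mean/SD
    of the per-fold selected-set sizes pooled over all runs.
    """
    results = list(results)
    if not results:
        raise ParameterError("stability_summary requires at least one result")
    note = ""
    if len(results) == 1:
        note = "single run: standard deviations degenerate to 0"
    accs = np.asarray([r.loocv_accuracy for r in results], dtype=float)
    sizes = np.asarray([s for r in results for s in r.fold_set_sizes], dtype=float)
    acc_mean = float(accs.mean())
    acc_sd = _sample_sd(accs)
    return StabilitySummary(
        n_runs=len(results),
        accuracy_mean=acc_mean,
        accuracy_sd=acc_sd,
        accuracy_cv=float(100.0 * acc_sd / acc_mean) if acc_mean > 0 else float("nan"),
        set_size_mean=float(sizes.mean()),
        set_size_sd=_sample_sd(sizes),
        note=note,
    )
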