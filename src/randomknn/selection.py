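"""Two-stage backward feature elimination driven by feature supports.

Direct selection — keep the top-ranked features after one support run —
is too aggressive for very high-dimensional data, so elimination proceeds
in recursive rounds.  Stage 1 (*geometric*): each iteration recomputes
supports on the surviving features and keeps the top ``ceil(p * (1 - q))``,
so the dimension follows a geometric progression down towards ``min_dim``.
The criterion for a feature *set* is the mean accuracy of the r base
classifiers; the iteration just before the accuracy maximum (the *pre-max*
iteration) seeds stage 2.  Stage 2 (*linear*): drop the ``d`` lowest-ranked
features per iteration and return the set with the best mean accuracy.

Both stages are deterministic under the master seed: every random draw
comes from one generator chained through the iterations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, RknnParams
from .ensemble import RknnModel, fit_rknn
from .exceptions import ParameterError
from .support import SupportRanking, compute_supports

__all__ = [
    "IterationRecord",
    "SelectionTrace",
    "SelectionResult",
    "n_geometric_iterations",
    "n_linear_steps",
    "geometric_retention",
    "pre_max_index",
    "best_index",
    "geometric_stage",
    "linear_stage",
    "rknn_fs",
]


def n_geometric_iterations(p: int, q: float, min_dim: int = 4) -> int:
    """Closed-form stage-1 iteration count: floor(ln(min_dim/p) / ln(1-q))."""
    if p <= min_dim:
        return 0
    return int(math.floor(math.log(min_dim / p) / math.log(1.0 - q)))


def geometric_retention(p_prev: int, q: float) -> int:
    """Features kept by one geometric iteration: ceil(p_prev * (1 - q))."""
    return int(math.ceil(p_prev * (1.0 - q)))


def n_linear_steps(p_start: int, d: int, min_dim: int = 4) -> int:
    """Closed-form stage-2 elimination-step count: floor((p_start - min_dim) / d)."""
    if p_start <= min_dim:
        return 0
    return (p_start - min_dim) // d


def pre_max_index(accuracies: Sequence[float]) -> int:
    """0-based index of the pre-max iteration.

    The earliest iteration attaining the maximal mean accuracy, minus one —
    the larger feature set just before the peak (conservative on ties).
    Clamped to 0 when the peak is the first iteration.
    """
    accs = np.asarray(accuracies, dtype=float)
    if accs.size == 0:
        raise ParameterError("empty accuracy sequence")
    return max(int(np.argmax(accs)) - 1, 0)


def best_index(accuracies: Sequence[float]) -> int:
    """Earliest iteration attaining the maximal mean accuracy (0-based)."""
    accs = np.asarray(accuracies, dtype=float)
    if accs.size == 0:
        raise ParameterError("empty accuracy sequence")
    return int(np.argmax(accs))


@dataclass(frozen=True)
class IterationRecord:
    """One elimination iteration: the evaluated set and its criterion."""

    index: int
    feature_ids: tuple[str, ...]
    n_features: int
    ranking: SupportRanking
    accuracy: float


@dataclass(frozen=True)
class SelectionTrace:
    """Full record of one elimination stage, for inspection and plotting."""

    stage: str  # "geometric" or "linear"
    iterations: tuple[IterationRecord, ...]
    chosen_index: int

    @property
    def accuracies(self) -> list[float]:
        return [it.accuracy for it in self.iterations]

    @property
    def sizes(self) -> list[int]:
        return [it.n_features for it in self.iterations]

    @property
    def chosen(self) -> IterationRecord:
        return self.iterations[self.chosen_index]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stage,
                "iteration": [it.index for it in self.iterations],
                "n_features": self.sizes,
                "mean_accuracy": self.accuracies,
                "features": [";".join(it.feature_ids) for it in self.iterations],
            }
        )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of RKNN-FS: the selected features and the final model."""

    selected: tuple[str, ...]
    model: RknnModel
    geometric_trace: SelectionTrace
    linear_trace: SelectionTrace | None

    def traces_frame(self) -> pd.DataFrame:
        frames = [self.geometric_trace.as_frame()]
        if self.linear_trace is not None:
            frames.append(self.linear_trace.as_frame())
        return pd.concat(frames, ignore_index=True)

    def write_traces(self, path: str | Path) -> None:
        self.traces_frame().to_csv(path, sep="\t", index=False)

    def write_selected(self, path: str | Path) -> None:
        Path(path).write_text("".join(f + "\n" for f in self.selected))


def _evaluate(
    dataset: Dataset,
    feature_ids: Sequence[str],
    params: RknnParams,
    rng: np.random.Generator,
    index: int,
) -> IterationRecord:
    sub = dataset.features_by_id(feature_ids)
    ranking = compute_supports(sub, params, rng=rng)
    return IterationRecord(
        index=index,
        feature_ids=tuple(feature_ids),
        n_features=len(feature_ids),
        ranking=ranking,
        accuracy=ranking.mean_acc,
    )


def geometric_stage(
    dataset: Dataset,
    params: RknnParams,
    rng: np.random.Generator | None = None,
) -> SelectionTrace:
    """Stage-1 geometric elimination.

    Iteration 1 computes supports on all p features; every later iteration
    keeps the top ``ceil(p_prev * (1-q))`` features by support rank and
    recomputes.  Runs ``floor(ln(min_dim/p)/ln(1-q))`` iterations, stopping
    earlier if the next retention would fall below ``min_dim`` (the guard
    wins when the closed form disagrees).  The chosen iteration is pre-max:
    the one just before the mean-accuracy peak.
    """
    p = dataset.n_features
    if p <= params.min_dim:
        warnings.warn(
            f"p={p} <= min_dim={params.min_dim}: nothing to eliminate; "
            "evaluating the full feature set only",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.zscore:
        dataset = dataset.zscore()
        params = replace(params, zscore=False)
    ni = n_geometric_iterations(p, params.q, params.min_dim)
    iterations: list[IterationRecord] = []
    current = list(dataset.feature_ids)
    iterations.append(_evaluate(dataset, current, params, rng, index=1))
    for i in range(2, ni + 1):
        keep = geometric_retention(len(current), params.q)
        if keep < params.min_dim:
            break
        current = iterations[-1].ranking.top_features(keep)
        iterations.append(_evaluate(dataset, current, params, rng, index=i))
    return SelectionTrace(
        stage="geometric",
        iterations=tuple(iterations),
        chosen_index=pre_max_index([it.accuracy for it in iterations]),
    )


def linear_stage(
    dataset: Dataset,
    start_features: Sequence[str],
    params: RknnParams,
    rng: np.random.Generator | None = None,
) -> SelectionTrace:
    """Stage-2 linear reduction from the pre-max feature set.

    Iteration 1 evaluates the start set; each of the
    ``floor((p_start - min_dim) / d)`` elimination steps drops the ``d``
    lowest-ranked features and re-evaluates.  The chosen iteration is the
    accuracy argmax (earliest on ties).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.zscore:
        dataset = dataset.zscore()
        params = replace(params, zscore=False)
    start = list(start_features)
    p_start = len(start)
    iterations = [_evaluate(dataset, start, params, rng, index=1)]
    if p_start <= params.min_dim:
        warnings.warn(
            f"start set of size {p_start} is at or below min_dim="
            f"{params.min_dim}; returned unchanged",
            stacklevel=2,
        )
        return SelectionTrace("linear", tuple(iterations), chosen_index=0)
    steps = n_linear_steps(p_start, params.d, params.min_dim)
    current = start
    for i in range(2, steps + 2):
        keep = len(current) - params.d
        current = iterations[-1].ranking.top_features(keep)
        iterations.append(_evaluate(dataset, current, params, rng, index=i))
    return SelectionTrace(
        stage="linear",
        iterations=tuple(iterations),
        chosen_index=best_index([it.accuracy for it in iterations]),
    )


def rknn_fs(
    dataset: Dataset,
    params: RknnParams,
    stage1_only: bool = False,
) -> SelectionResult:
    """Full RKNN-FS backward elimination; deterministic under ``params.seed``.

    Runs the geometric stage, passes the pre-max feature set to the linear
    stage, and returns the linear stage's best feature set together with a
    final Random KNN model fitted on it.  With ``stage1_only=True`` the
    linear stage is skipped and the geometric stage's best-accuracy
    iteration provides the selected set (the protocol used when only a fast
    screen is wanted).
    """
    if params.zscore:
        dataset = dataset.zscore()
        params = replace(params, zscore=False)
    rng = np.random.default_rng(params.seed)
    geo = geometric_stage(dataset, params, rng=rng)
    if stage1_only:
        selected = geo.iterations[best_index(geo.accuracies)].feature_ids
        model = fit_rknn(dataset.features_by_id(selected), params)
        return SelectionResult(tuple(selected), model, geo, None)
    start = geo.chosen.feature_ids
    lin = linear_stage(dataset, start, params, rng=rng)
    selected = lin.chosen.feature_ids
    model = fit_rknn(dataset.features_by_id(selected), params)
    return SelectionResult(tuple(selected), model, geo, lin)
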