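"""Synthetic small-n, large-p datasets with planted informative features.

Real expression matrices in this regime have a few dozen to a few hundred
samples, thousands of features, and only a small subset of features that
actually track the class structure.  The generator emulates exactly that:
independent standard-normal noise features, plus ``n_informative`` planted
features whose class means sit on a grid with spacing ``shift`` (in units
of the noise SD).  The planted identifiers are returned as ground truth so
recovery by a feature-selection procedure can be scored.

It deliberately does NOT model microarray technical artefacts — probe
effects, batch effects, heavy tails, feature correlation — so results on
these data bound what the algorithms can do under clean Gaussian signal,
not what they will do on any particular real platform.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .data_model import Dataset
from .exceptions import ParameterError

__all__ = ["SyntheticSpec", "generate", "tiny_fixture", "TINY_FIXTURE_VALUES"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Attributes
    ----------
    n, p, c
        Samples, features, classes.
    n_informative
        Number of planted class-informative features (positions drawn at
        random among the p columns).
    shift
        Mean separation between adjacent classes on a planted feature, in
        noise-SD units.  0 means the planted features are pure noise too.
    class_proportions
        Expected class frequencies (default: balanced).  Must be positive
        and sum to 1.
    exact_counts
        Assign class sizes deterministically by largest remainder instead
        of multinomial sampling — for experiments needing exact control.
    seed
        Generator seed; identical specs give bit-identical datasets.
    """

    n: int = 60
    p: int = 2000
    c: int = 2
    n_informative: int = 10
    shift: float = 1.5
    class_proportions: tuple[float, ...] | None = None
    exact_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.c:
            raise ParameterError(f"n={self.n} cannot host c={self.c} classes")
        if self.c < 2:
            raise ParameterError(f"need at least 2 classes, got c={self.c}")
        if not (0 <= self.n_informative <= self.p):
            raise ParameterError("n_informative must lie in [0, p]")
        if self.shift < 0:
            raise ParameterError(f"shift must be non-negative, got {self.shift}")
        if self.class_proportions is not None:
            props = tuple(float(v) for v in self.class_proportions)
            if len(props) != self.c:
                raise ParameterError("class_proportions must have length c")
            if any(v <= 0 for v in props) or abs(sum(props) - 1.0) > 1e-9:
                raise ParameterError("class_proportions must be positive and sum to 1")
            object.__setattr__(self, "class_proportions", props)


def _class_names(c: int) -> list[str]:
    if c <= 26:
        return list(string.ascii_uppercase[:c])
    return [f"C{i + 1:02d}" for i in range(c)]


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    props = np.asarray(
        spec.class_proportions
        if spec.class_proportions is not None
        else [1.0 / spec.c] * spec.c
    )
    if spec.exact_counts:
        raw = props * spec.n
        counts = np.floor(raw).astype(int)
        remainder = raw - counts
        short = spec.n - counts.sum()
        for j in np.argsort(-remainder)[:short]:
            counts[j] += 1
        counts = np.maximum(counts, 1)
        while counts.sum() > spec.n:
            counts[int(np.argmax(counts))] -= 1
        codes = np.repeat(np.arange(spec.c), counts)
        rng.shuffle(codes)
        return codes
    for _ in range(100):
        codes = rng.choice(spec.c, size=spec.n, p=props)
        if len(np.unique(codes)) == spec.c:
            return codes
    raise ParameterError(
        "could not draw labels containing every class; n is too small for "
        "the requested proportions (use exact_counts=True)"
    )


def generate(spec: SyntheticSpec) -> tuple[Dataset, list[str]]:
    """Draw one dataset from the spec; returns (dataset, planted feature ids).

    Noise features are i.i.d. standard normal.  Each planted feature adds a
    class-dependent offset ``(code - (c-1)/2) * shift`` so adjacent classes
    are ``shift`` noise-SDs apart on that feature.
    """
    rng = np.random.default_rng(spec.seed)
    codes = _draw_labels(spec, rng)
    X = rng.standard_normal((spec.n, spec.p))
    planted = np.sort(rng.choice(spec.p, size=spec.n_informative, replace=False))
    offsets = (np.arange(spec.c) - (spec.c - 1) / 2.0) * spec.shift
    for j in planted:
        X[:, j] += offsets[codes]
    names = _class_names(spec.c)
    width = max(4, len(str(spec.p)))
    feature_ids = [f"G{j + 1:0{width}d}" for j in range(spec.p)]
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n)]
    dataset = Dataset(
        X,
        [names[k] for k in codes],
        feature_ids=feature_ids,
        sample_ids=sample_ids,
    )
    return dataset, [feature_ids[j] for j in planted]


#: Fixed 8-sample x 6-feature two-class fixture.  f1/f2 separate the
#: classes (A clustered near (0,0), B near (4,4)); f3-f6 are small
#: uninformative integers.  Values are integers so every pairwise distance
#: is exactly representable and checkable by hand.
TINY_FIXTURE_VALUES = {
    "X": [
        # f1 f2 f3 f4 f5 f6
        [0, 0, 2, 1, 0, 1],  # S1 A
        [1, 0, 0, 2, 1, 1],  # S2 A
        [0, 1, 1, 0, 2, 0],  # S3 A
        [1, 1, 2, 1, 0, 0],  # S4 A
        [4, 4, 0, 2, 1, 1],  # S5 B
        [5, 4, 1, 0, 2, 1],  # S6 B
        [4, 5, 2, 1, 0, 0],  # S7 B
        [5, 5, 0, 2, 1, 0],  # S8 B
    ],
    "y": ["A", "A", "A", "A", "B", "B", "B", "B"],
    "feature_ids": ["f1", "f2", "f3", "f4", "f5", "f6"],
    "sample_ids": ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8"],
}


def tiny_fixture() -> Dataset:
    """The fixed hand-checkable dataset used for exact-value tests."""
    return Dataset(
        np.asarray(TINY_FIXTURE_VALUES["X"], dtype=float),
        TINY_FIXTURE_VALUES["y"],
        feature_ids=TINY_FIXTURE_VALUES["feature_ids"],
        sample_ids=TINY_FIXTURE_VALUES["sample_ids"],
    )
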