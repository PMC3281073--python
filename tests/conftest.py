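import numpy as np
import pytest

from randomknn import Dataset, RknnParams, SyntheticSpec, generate, tiny_fixture


@pytest.fixture
def tiny() -> Dataset:
    return tiny_fixture()


@pytest.fixture
def small_synth() -> tuple[Dataset, list[str]]:
    """40 samples x 30 features, 2 classes, 5 planted features."""
    spec = SyntheticSpec(n=40, p=30, c=2, n_informative=5, shift=1.5, seed=7)
    return generate(spec)


@pytest.fixture
def fast_params() -> RknnParams:
    """Small ensemble for quick structural tests."""
    return RknnParams(k=3, r=50, seed=11)


def random_labelled_instance(rng: np.random.Generator, n_max=50, p_max=20, c_max=3):
    """A random dense instance for oracle-equivalence checks."""
    n = int(rng.integers(5, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    c = int(rng.integers(2, c_max + 1))
    X = np.round(rng.normal(size=(n, p)), 3)  # rounding provokes distance ties
    y = rng.choice([chr(65 + i) for i in range(c)], size=n)
    while len(set(y)) < 2:
        y = rng.choice([chr(65 + i) for i in range(c)], size=n)
    return X, [str(v) for v in y]
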