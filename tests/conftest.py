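import numpy as np
import pandas as pd
import pytest


def make_separable(n: int = 400, n_noise: int = 2, seed: int = 0, shrink: float = 0.0):
    """Two-class data perfectly separable on one variable.

    The informative variable lives on [0, 1] for class 0 and [2, 3] for
    class 1 (disjoint supports, so any threshold in (1, 2) separates);
    noise variables are uniform on [0, 1] for both classes. Split
    thresholds land exactly on observed training values, so holdout sets
    should be drawn with ``shrink > 0`` to pull their supports strictly
    inside the training supports (otherwise holdout points can fall in the
    sliver beyond the largest training value of their class).
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    info = np.where(
        y == 1,
        rng.uniform(2 + shrink, 3, size=n),
        rng.uniform(0, 1 - shrink, size=n),
    )
    data = {"informative": info}
    for j in range(n_noise):
        data[f"noise{j}"] = rng.uniform(0, 1, size=n)
    return pd.DataFrame(data), y.astype(np.int64)


@pytest.fixture
def separable():
    return make_separable()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
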