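import numpy as np
import pytest

from mofuzz.sc_io import CountMatrix


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """5 genes x 4 cells with a hand-checkable detection pattern."""
    counts = np.array(
        [
            [0, 2, 5, 1],
            [3, 0, 0, 2],
            [0, 0, 7, 0],
            [1, 1, 1, 1],
            [0, 4, 2, 0],
        ],
        dtype=float,
    )
    return CountMatrix(counts, [f"g{i}" for i in range(5)], [f"c{i}" for i in range(4)])


@pytest.fixture
def separated_points() -> tuple[np.ndarray, np.ndarray]:
    """Two tight, far-apart 2-D clusters of 20 points each, with labels."""
    rng = np.random.default_rng(42)
    a = rng.normal([0, 0], 0.05, size=(20, 2))
    b = rng.normal([10, 10], 0.05, size=(20, 2))
    labels = np.repeat([0, 1], 20)
    return np.vstack([a, b]), labels


def random_membership(rng: np.random.Generator, cl: int, n: int) -> np.ndarray:
    """Random column-stochastic membership matrix."""
    u = rng.uniform(size=(cl, n))
    return u / u.sum(axis=0)
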