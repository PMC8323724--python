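import numpy as np
import pytest

from fcki import NumericDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def dataset(values) -> NumericDataset:
    """Shorthand: build a NumericDataset from a nested list / array."""
    return NumericDataset(np.asarray(values, dtype=float))


@pytest.fixture
def complete_10x10(rng):
    return NumericDataset(rng.normal(size=(10, 10)))


@pytest.fixture
def complete_10x5(rng):
    return NumericDataset(rng.normal(size=(10, 5)))


def random_incomplete(rng, n, m, frac=0.15):
    """A random matrix with ~frac missing cells, every column and row keeping
    at least one observed value."""
    x = rng.normal(size=(n, m))
    k = max(1, int(round(frac * n * m)))
    flat = rng.choice(n * m, size=k, replace=False)
    mask = np.zeros(n * m, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(n, m)
    mask[np.flatnonzero(mask.all(axis=1)), 0] = False
    for j in np.flatnonzero(mask.all(axis=0)):
        mask[int(rng.integers(n)), j] = False
    x[mask] = np.nan
    return x
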