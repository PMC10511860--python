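import numpy as np
import pytest

from ntfcv.tensor_model import WeightedTensor


@pytest.fixture
def small_full_tensor() -> WeightedTensor:
    """Fully observed 2x2x1 tensor holding 1..4."""
    vals = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
    return WeightedTensor(values=vals, weights=np.ones((2, 2, 1)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_weighted_tensor(
    rng: np.random.Generator, shape=(5, 4, 3), missing: float = 0.0
) -> WeightedTensor:
    vals = rng.uniform(size=shape)
    weights = np.ones(shape)
    if missing > 0:
        n = vals.size
        drop = rng.choice(n, size=int(missing * n), replace=False)
        weights.flat[drop] = 0.0
        vals.flat[drop] = np.nan
    return WeightedTensor(values=vals, weights=weights)
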