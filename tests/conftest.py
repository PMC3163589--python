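import numpy as np
import pytest

from seqibd import DistanceMatrix

from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_dm(values, ids=None) -> DistanceMatrix:
    """Build a DistanceMatrix from any square array (symmetrized, hollow)."""
    values = np.asarray(values, dtype=float)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    n = values.shape[0]
    if ids is None:
        ids = tuple(f"t{i}" for i in range(n))
    return DistanceMatrix(tuple(ids), values)


def random_dm(n: int, rng: np.random.Generator, scale: float = 1.0) -> DistanceMatrix:
    return make_dm(rng.uniform(0, scale, (n, n)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
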