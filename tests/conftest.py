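import numpy as np
import pytest

from m3s.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def count_matrix(rng):
    """Small integer count matrix with zeros (Poisson-ish)."""
    values = rng.poisson(5.0, size=(6, 60)).astype(float)
    values[0, :10] = 0
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(6)],
        [f"s{j}" for j in range(60)],
    )


@pytest.fixture
def real_matrix(rng):
    """Continuous matrix including negative values (already log-scale)."""
    values = rng.normal(2.0, 1.0, size=(4, 50))
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(4)],
        [f"s{j}" for j in range(50)],
    )
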