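import numpy as np
import pytest

from emci import Ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def small_ensemble():
    """3 x 2 hand-sized ensemble with easy arithmetic."""
    return Ensemble(
        np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 9.0]]), ("A", "B"), "toy"
    )


@pytest.fixture
def normal_ensemble(rng):
    """500 x 8 independent normal ensemble with distinct means/SDs."""
    means = np.linspace(-2.0, 2.0, 8)
    sds = np.linspace(0.5, 2.0, 8)
    values = rng.standard_normal((500, 8)) * sds + means
    return Ensemble(values, tuple(f"x{j}" for j in range(8)), "normal")
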