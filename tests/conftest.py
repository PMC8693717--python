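import numpy as np
import pytest

from robustgxe import Hyperparameters, MarginalDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hyper():
    return Hyperparameters()


@pytest.fixture
def toy_design(rng):
    """A small marginal design (n=12, q=2, m=1) with a real main effect."""
    n, q, m = 12, 2, 1
    E = rng.standard_normal((n, q))
    C = rng.standard_normal((n, m))
    x = rng.standard_normal(n)
    y = E @ np.array([0.4, 0.2]) + 0.3 * C[:, 0] + 1.5 * x \
        + 0.8 * x * E[:, 0] + rng.standard_normal(n)
    return MarginalDesign(y=y, E=E, C=C, x=x)
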