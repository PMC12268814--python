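import numpy as np
import pytest

from plexkit.curve_model import SigmoidParams


def random_valid_params(rng: np.random.Generator) -> SigmoidParams:
    """Draw one parameter vector from the realistic qPCR regime."""
    return SigmoidParams(
        fm=rng.uniform(100.0, 5000.0),
        fb=rng.uniform(0.0, 500.0),
        sc=rng.uniform(0.2, 3.0),
        cs=rng.uniform(10.0, 40.0),
        asym=rng.uniform(0.2, 5.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def symmetric_params() -> SigmoidParams:
    return SigmoidParams(fm=1.0, fb=0.0, sc=1.0, cs=0.0, asym=1.0)


@pytest.fixture
def asymmetric_params() -> SigmoidParams:
    return SigmoidParams(fm=1.0, fb=0.0, sc=1.0, cs=20.0, asym=2.0)
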