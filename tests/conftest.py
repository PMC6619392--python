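import numpy as np
import pytest

from predhet import single_predictor_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def large_single_cohort():
    """One large draw from the single-predictor population, shared across
    tests that only need a consistent (y, X) sample."""
    from predhet import generate_cohort

    rng = np.random.default_rng(42)
    return generate_cohort(200_000, single_predictor_model(), rng)
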