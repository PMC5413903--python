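import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from clonetrace import SimParams, generate_library  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_library():
    """A 5,000-barcode library for pipeline round-trip tests."""
    return generate_library(5_000, barcode_length=30, seed=42)


@pytest.fixture(scope="session")
def scaled_params():
    """Scaled-down split-dish experiment used across simulator tests.

    20,000 seeded cells at MOI 0.63 (the Thy1/control experiments' MOI),
    a 10^6-barcode library, and per-dish quotas around 75 barcodes, which
    reproduces the experiments' few-percent reprogramming efficiency at
    this population size.
    """
    return SimParams(
        n_seeded=20_000,
        moi=0.63,
        diversity=1_000_000,
        loss=0.3,
        mu=75.0,
        si=8.0,
    )
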