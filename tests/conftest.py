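import numpy as np
import pytest

from modgap import calibrate_thresholds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def table_n40():
    """A fully calibrated threshold table for n=40 at standard settings.

    Shared across tests; calibration is deterministic given the seed.
    """
    return calibrate_thresholds(40, kmax=8, alpha_per_k=0.01, null_reps=1000, B=100, seed=11)


@pytest.fixture(scope="session")
def table_n40_coarse():
    """A cheaper table for tests that only need a plausible decision rule."""
    return calibrate_thresholds(40, kmax=8, alpha_per_k=0.01, null_reps=400, B=50, seed=7)
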