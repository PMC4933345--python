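import numpy as np
import pytest

from icretention import default_params, simulate_run


@pytest.fixture(scope="session")
def bmmnc_params():
    """Calibrated mononuclear-cell defaults (lognormal median 7.0 um)."""
    return default_params("BMMNC")


@pytest.fixture(scope="session")
def msc_params():
    """Calibrated stromal-cell defaults (median 11.5 um, mean 12.2 um)."""
    return default_params("MSC")


@pytest.fixture(scope="session")
def small_bmmnc_run(bmmnc_params):
    """One small simulated injection (1e5 cells) reused across tests."""
    return simulate_run(bmmnc_params, 100_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
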