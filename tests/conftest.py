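import numpy as np
import pytest

import flim_bayes as fb

PERIOD = 12.5
TAU_SHORT = 0.48
TAU_LONG = 4.03


@pytest.fixture(scope="session")
def binning():
    """Default acquisition: 256 bins over a 10 ns window, 12.5 ns period."""
    return fb.default_binning()


@pytest.fixture(scope="session")
def irf(binning):
    return fb.default_irf(binning)


@pytest.fixture(scope="session")
def delta_irf(binning):
    return fb.InstrumentResponse.delta(binning, bin_index=1)


@pytest.fixture(scope="session")
def theta_mix():
    return fb.DecayParameters(
        f_short=0.3, f_long=0.6, tau_short=TAU_SHORT, tau_long=TAU_LONG, period=PERIOD
    )


@pytest.fixture(scope="session")
def full_period_binning():
    """Recorded window equal to the excitation period (50 bins of 0.25 ns)."""
    return fb.TimeBinning.uniform(50, window=PERIOD)


@pytest.fixture(scope="session")
def fitter(binning, irf):
    return fb.FixedLifetimeGridFitter(
        binning, irf, tau_short=TAU_SHORT, tau_long=TAU_LONG, period=PERIOD
    )
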