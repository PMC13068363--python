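import numpy as np
import pytest

from protomorph import synth


@pytest.fixture(scope="session")
def burst_run_seed7():
    """The default burst potential log (seed 7) used by recovery tests."""
    return synth.gen_burst_potential_series(synth.BurstSeriesParams(seed=7))


@pytest.fixture(scope="session")
def three_phase_records():
    """Noise-free three-phase impedance scan with default trajectory."""
    return synth.gen_three_phase_impedance(synth.ThreePhaseImpedanceParams())


@pytest.fixture(scope="session")
def voltammetry_noiseless():
    return synth.gen_voltammetry_fixtures()


@pytest.fixture(scope="session")
def sierpinski_1024():
    """Sierpinski triangle mask via the bitwise-AND construction."""
    n = 1024
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (ii & jj) == 0
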