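import numpy as np
import pytest

from dwi_eip import PhantomSpec, make_phantom, simulate_stacks


@pytest.fixture(scope="session")
def noiseless_ramp_spec():
    """Single-slice phantom, no noise, linear phase ramps only."""
    return PhantomSpec(n_slices=1, noise_sigma=0.0, phase_poly_amplitude=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_ramp_stacks(noiseless_ramp_spec):
    truth = make_phantom(noiseless_ramp_spec)
    return truth, simulate_stacks(truth, noiseless_ramp_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
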