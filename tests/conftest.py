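import numpy as np
import pytest

from p53cycle import default_parameters, integrate, make_initial_state


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def traj_ir0(params):
    """Normal-condition run, reused by every test that needs the baseline
    limit cycle."""
    return integrate(params, make_initial_state(0.0), 150.0, ir_dose=0.0)


@pytest.fixture(scope="session")
def traj_ir5(params):
    """A strongly irradiated run for invariant checks."""
    return integrate(params, make_initial_state(5.0), 150.0, ir_dose=5.0)
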