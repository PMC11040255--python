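import numpy as np
import pytest

import tritroph as tt


@pytest.fixture(scope="session")
def ref_params() -> tt.Params:
    """Reference parameter set: no reproductive costs, certain infection."""
    return tt.make_params()


@pytest.fixture(scope="session")
def ref_state() -> tt.SystemState:
    return tt.REFERENCE_INITIAL_STATE


@pytest.fixture(scope="session")
def ref_trajectory(ref_params, ref_state) -> tt.Trajectory:
    """Deterministic reference run to t = 2000 (reused across tests)."""
    return tt.integrate(ref_state, ref_params, t_max=2000.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240424)
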