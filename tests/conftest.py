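import numpy as np
import pytest

import synaptrans as st


@pytest.fixture
def basic_p():
    return st.basic_parameters()


@pytest.fixture
def basic_d():
    return st.basic_delays()


@pytest.fixture
def short_delays():
    """Short-delay configuration used by the recycling sweeps."""
    return st.basic_delays(tau_a=1.0, tau_b=2.0, tau_r=3.0, tau_e=5.0)


@pytest.fixture
def decay_system(basic_p):
    """No synthesis, no recycling: x decays as exp(-(k_rx+k_dx) t)."""
    return basic_p.replace(k_x=0.0, k_x0=0.0, k_rz=0.0)


@pytest.fixture
def fast_settings():
    """Short horizon for unit tests that only need a valid trajectory."""
    return st.IntegrationSettings(h=0.01, t_end=50.0)


@pytest.fixture(autouse=True)
def _quiet_range_warnings():
    """Unit tests sweep parameters outside the reference scan ranges on
    purpose; the advisory warning is tested explicitly elsewhere."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", st.ParameterRangeWarning)
        yield


def manufactured_trajectory(fn, dfn, t_end=50.0, h=0.01):
    """Trajectory whose x component follows an analytic function."""
    t = np.arange(0.0, t_end + h / 2, h)
    states = np.zeros((t.size, 3))
    states[:, 0] = fn(t)
    derivs = np.zeros_like(states)
    derivs[:, 0] = dfn(t)
    return st.Trajectory(t=t, states=states, derivs=derivs, h=h)
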