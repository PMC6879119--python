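import numpy as np
import pytest

from pwidsim import ParameterSet, calibrate, sample_parameter_sets


def table1_mean_params() -> ParameterSet:
    """A deterministic, representative parameter set (distribution means)."""
    return ParameterSet(
        mu_b=1 / 69.3,
        mu_ov=0.0062,
        theta=0.025,
        xi=1 / 13.70,
        rho=1 / 0.62,
        m_inv=1.85,
        rr_history=5.03,
        rr_oat=0.56,
        rr_oat_out=2.43,
        rr_oat_in=2.10,
        rr_oat_ov=0.21,
        target_prev_nonidu=0.090,
        target_prev_pwid=0.011,
        target_prop_unassisted=0.17,
        target_oat_coverage=0.21,
    )


@pytest.fixture(scope="session")
def mean_params() -> ParameterSet:
    return table1_mean_params()


@pytest.fixture(scope="session")
def mean_calibrated(mean_params):
    cal = calibrate(mean_params)
    assert cal.converged
    return cal


@pytest.fixture(scope="session")
def sampled_sets():
    return sample_parameter_sets(50, seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
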