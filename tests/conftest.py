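import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from co2fate import AnalysisConfig, EndmemberSet, FractionationFactors
from co2fate.synthetic import SyntheticFieldParams, generate_control_field, generate_field
from co2fate.thermometry import load_default_calibrations


@pytest.fixture(scope="session")
def endmembers():
    return EndmemberSet()


@pytest.fixture(scope="session")
def factors():
    return FractionationFactors()


@pytest.fixture(scope="session")
def calibrations():
    return load_default_calibrations()


@pytest.fixture()
def config():
    return AnalysisConfig(rng_seed=42)


@pytest.fixture(scope="session")
def noiseless_params():
    return SyntheticFieldParams(
        seed=3,
        noise_d13c=0.0,
        noise_co2_he3_rel=0.0,
        noise_clumped=0.0,
        injectate_d13c_sd=0.0,
        d13ch3d_offset=0.0,
        d12ch2d2_offset=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_field(noiseless_params):
    return generate_field(noiseless_params)


@pytest.fixture(scope="session")
def noisy_field():
    return generate_field(SyntheticFieldParams(seed=11))


@pytest.fixture(scope="session")
def control_field():
    return generate_control_field(SyntheticFieldParams(seed=11))


def rayleigh_oracle(delta_i: float, f: float, alpha: float, n_steps: int = 10**6) -> float:
    """Independent incremental-removal oracle for open-system Rayleigh
    fractionation: remove the pool in ``n_steps`` equal mass increments, each
    carrying the instantaneous alpha-fractionated isotope ratio."""
    m = np.linspace(1.0, f, n_steps + 1)
    dm = m[:-1] - m[1:]
    log_ratio = np.sum(np.log((m[:-1] - alpha * dm) / m[1:]))
    return (1000.0 + delta_i) * np.exp(log_ratio) - 1000.0
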