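import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xrfdwt import LineTable, Spectrum
from xrfdwt import synthdata as sd

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_cfg() -> sd.SimConfig:
    """Default generator configuration (4096 channels, SDD-like resolution)."""
    return sd.SimConfig()


@pytest.fixture(scope="session")
def cal(sim_cfg):
    return sim_cfg.calibration


@pytest.fixture(scope="session")
def lines() -> LineTable:
    return LineTable.default()


@pytest.fixture(scope="session")
def blank_spectrum(sim_cfg):
    """One noisy analyte-free spectrum with its truth (seed 2)."""
    return sd.simulate_spectrum({}, sim_cfg, seed=2)


@pytest.fixture(scope="session")
def cr_spectrum(sim_cfg):
    """A spectrum with a tall Cr peak over the continuum (seed 1)."""
    return sd.simulate_spectrum({"Cr": 500.0}, sim_cfg, seed=1)


def rms(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(a))))


@pytest.fixture(scope="session")
def rms_fn():
    return rms
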