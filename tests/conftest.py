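"""Shared fixtures: simulated subjects, recordings, and a small cohort."""

import numpy as np
import pytest

from aeropower import simulate_cohort, simulate_cpet
from aeropower.profiles import SubjectProfile
from aeropower.simulate import CpetModel


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile(
        id="s001",
        sex="male",
        age=28.0,
        mass=75.0,
        height=177.0,
        vo2max_true=4000.0,
        vat_fraction=0.65,
        ve_max_true=140.0,
        hr_max=185.0,
    )


@pytest.fixture(scope="session")
def recording(subject):
    """A default-noise simulated recording."""
    return simulate_cpet(subject, seed=12345)


@pytest.fixture(scope="session")
def quiet_recording(subject):
    """A very low-noise recording (for closed-form feature checks)."""
    model = CpetModel(noise_vo2=1e-4, noise_vco2=1e-4, noise_ve=1e-4,
                      noise_rf=0.01, noise_hr=0.01)
    return simulate_cpet(subject, seed=12345, model=model)


@pytest.fixture(scope="session")
def noiseless_recording(subject):
    model = CpetModel(noise_vo2=0.0, noise_vco2=0.0, noise_ve=0.0,
                      noise_rf=0.0, noise_hr=0.0)
    return simulate_cpet(subject, seed=0, model=model)


@pytest.fixture(scope="session")
def cohort20():
    """Small default cohort shared across feature/selection tests."""
    return simulate_cohort(20, seed=424242)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
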