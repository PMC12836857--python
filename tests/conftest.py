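"""Shared fixtures: slice plans and a grid-commensurate identity analyte."""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from slicelogp import AcquisitionParams, Analyte, PartitionSample
from slicelogp.automation import default_plan


@pytest.fixture(scope="session")
def plan600():
    """Valid 24%-gradient plan at the 600 MHz (14.1 T) field."""
    return default_plan(600.13)


@pytest.fixture(scope="session")
def plan400():
    """Valid 16%-gradient plan at the 400 MHz (9.4 T) field."""
    return default_plan(400.13)


@pytest.fixture
def identity_analyte():
    """Equal linewidths/relaxation in both phases and a phase shift
    separation of exactly 2.5 ppm — with the default acquisition grid
    (td 16384, 10 ppm window, zero-fill x2 -> 10/16384 ppm per bin) the two
    lines sit an integer number of bins apart, so both integration windows
    sample congruent lineshapes and all processing factors cancel exactly in
    the integral ratio."""
    return Analyte("identity-probe", 1, -72.5, -75.0, 2.0, 2.0, 3.0, 3.0, 0.6, 0.6)


@pytest.fixture
def identity_sample(identity_analyte):
    def make(logp_true: float) -> PartitionSample:
        return PartitionSample(identity_analyte, logp_true, 0.05)

    return make


@pytest.fixture
def quiet_params():
    """Noiseless defaults centred between the identity analyte's lines."""
    return AcquisitionParams(o1p=-73.75, noise_sigma=0.0, seed=1)
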