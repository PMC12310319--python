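import numpy as np
import pytest

from symptomnet.simulate import cohort_preset, sample_two_wave


@pytest.fixture(scope="session")
def preset():
    return cohort_preset()


@pytest.fixture(scope="session")
def two_wave_medium(preset):
    """One moderate two-wave draw shared by estimator tests."""
    return sample_two_wave(preset, 2000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
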