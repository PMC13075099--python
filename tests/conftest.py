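import numpy as np
import pytest

from fecgx.synthgen import NoiseSpec, add_noise, synth_clean_aecg, table1_cases


@pytest.fixture(scope="session")
def cases():
    return table1_cases()


@pytest.fixture(scope="session")
def clean_case1():
    """Clean 10 s record of the high-fetal-amplitude case at 500 Hz."""
    return synth_clean_aecg(table1_cases()[0], duration_s=10.0, fs=500.0, seed=11)


@pytest.fixture(scope="session")
def noisy_case1(clean_case1):
    return add_noise(clean_case1, NoiseSpec(target_snr_db=10.0, seed=12))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
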