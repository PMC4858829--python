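import numpy as np
import pytest

from hrmquant.melt_simulator import MeltModelParams

#: methylated fractions of the five-level calibration standard series
#: (measured endpoints: unmethylated standard 2.1 %, methylated 90.8 %)
STANDARD_FRACTIONS = (0.021, 0.243, 0.464, 0.686, 0.908)


@pytest.fixture(scope="session")
def default_params() -> MeltModelParams:
    return MeltModelParams()


@pytest.fixture(scope="session")
def noiseless_params() -> MeltModelParams:
    return MeltModelParams(noise_sd=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
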