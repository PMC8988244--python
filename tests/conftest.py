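import numpy as np
import pytest

from dimerfe.thermo import ThermoContext


@pytest.fixture(scope="session")
def thermo() -> ThermoContext:
    return ThermoContext(temperature=300.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
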