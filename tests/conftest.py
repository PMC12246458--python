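import numpy as np
import pytest

from dynia_mc import wheat_registry, sample_parameters
from dynia_mc.minicrop import generate_weather, reference_parameters, simulate


@pytest.fixture(scope="session")
def registry():
    return wheat_registry()


@pytest.fixture(scope="session")
def weather():
    return generate_weather(240, seed=42)


@pytest.fixture(scope="session")
def truth(registry):
    return reference_parameters(registry)


@pytest.fixture(scope="session")
def reference_run(truth, weather):
    return simulate(truth, weather)


@pytest.fixture(scope="session")
def samples_small(registry):
    return sample_parameters(registry, 60, seed=7)
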