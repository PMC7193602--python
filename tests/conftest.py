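import numpy as np
import pytest

from xegas.params import AcqParams
from xegas.phantom import PhantomConfig, make_phantom, simulate_measurement
from xegas.pipeline import build_references


@pytest.fixture(scope="session")
def acq() -> AcqParams:
    return AcqParams()


@pytest.fixture(scope="session")
def healthy_cohort():
    """Five healthy measured subjects (distinct seeds) at the default 64^3."""
    return [simulate_measurement(make_phantom(PhantomConfig(seed=s))) for s in range(5)]


@pytest.fixture(scope="session")
def references(healthy_cohort):
    return build_references(healthy_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
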