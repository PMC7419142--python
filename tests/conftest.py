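import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from cxring import fixtures
from cxring.circuit import WeightVector
from cxring.params import NeuronParams


@pytest.fixture(scope="session")
def params():
    return NeuronParams()


@pytest.fixture(scope="session")
def tiny_fly():
    """4-octant fly-style circuit (fast unit-test analogue)."""
    return fixtures.tiny_ring("fly")


@pytest.fixture(scope="session")
def tiny_locust():
    return fixtures.tiny_ring("locust")


@pytest.fixture(scope="session")
def small_weights():
    return WeightVector(3.0, 1.0, 1.0, -3.0, -3.0)


@pytest.fixture(scope="session")
def fly_results():
    from cxring.model import RingAttractorModel
    return RingAttractorModel.reference_results("fly")


@pytest.fixture(scope="session")
def locust_results():
    from cxring.model import RingAttractorModel
    return RingAttractorModel.reference_results("locust")


@pytest.fixture(scope="session")
def hybrid_results():
    from cxring.model import RingAttractorModel
    return RingAttractorModel.reference_results("hybrid")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
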