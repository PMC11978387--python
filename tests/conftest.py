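import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abdock.synthetic import ToyComplexSpec, make_pose_decoys, make_toy_complex

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec()


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_native(toy_complex):
    return toy_complex[0]


@pytest.fixture(scope="session")
def toy_annotation(toy_complex):
    return toy_complex[1]


@pytest.fixture(scope="session")
def translation_decoys(toy_native):
    """Decoys from pure progressive antigen translation (no rotation)."""
    schedule = [(0.0, t) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 30.0)]
    return make_pose_decoys(toy_native, schedule=schedule, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
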