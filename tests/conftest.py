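import random

import pytest
from hypothesis import HealthCheck, settings

import kissevo as kv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def species_tree():
    return kv.load_fixture("species_tree")


@pytest.fixture(scope="session")
def presence_matrix():
    return kv.load_fixture("presence_matrix")


@pytest.fixture(scope="session")
def kissr_tables():
    return kv.load_fixture("kissr_synteny")


@pytest.fixture(scope="session")
def kiss_tables():
    return kv.load_fixture("kiss_synteny")


@pytest.fixture(scope="session")
def predicted_kp10():
    return kv.load_fixture("predicted_kp10")


@pytest.fixture(scope="session")
def kp10_reference():
    return kv.load_fixture("kp10_reference")


def random_dna(n, rng, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20260927)
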