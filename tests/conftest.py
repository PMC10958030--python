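import random

import pytest
from hypothesis import HealthCheck, settings

from tradiskit import simlib

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """10 kb single-chromosome random genome."""
    return simlib.simulate_genome(10_000, 1, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return simlib.sample_truth(small_genome, 50, sigma=1.0, seed=11)


@pytest.fixture()
def rng():
    return random.Random(1234)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))
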