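import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from riscall.alignment import ReferenceSet
from riscall.config import PipelineConfig
from riscall.synthetic import SimulationSpec, simulate_dataset


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_dataset():
    """Error-free simulated dataset shared across end-to-end tests."""
    return simulate_dataset(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def default_refs(default_dataset):
    ds = default_dataset
    return ReferenceSet(genome=ds.genome, vector=ds.vector, vector_name="vector")


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
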