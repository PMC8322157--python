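import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epirate as ep

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_genome():
    """A 60 kb synthetic chromosome with planted gene/TE blocks."""
    sequences, annotation, partition = ep.simulate_genome(length=60_000, seed=11)
    return sequences, annotation, partition


@pytest.fixture(scope="session")
def ma1_1():
    return ep.build_pedigree("MA1_1")


@pytest.fixture(scope="session")
def small_experiment():
    """A simulated MA1_3-style experiment shared by calling/divergence tests."""
    cfg = ep.SimulationConfig(seed=5, pedigree_preset="MA1_3", n_regions=3000)
    ped, regions, states, counts = ep.simulate_experiment(cfg)
    return cfg, ped, regions, states, counts
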