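import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import squich as sq

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def example1():
    """The stylized deterministic tube: 1000 spheres and 10 cubes, one
    encoder per shape per round, competitors (0, 8, 89, 899)."""
    pop = sq.SpeciesPopulation(np.array([1000, 10]))
    sched = sq.ProbeSchedule.from_amounts(E=[1, 1, 1, 1], C=[0, 8, 89, 899])
    chem = sq.ChemistryParams(eta=1.0, eps=0.0)
    return pop, sched, chem


@pytest.fixture
def ideal_chem():
    return sq.ChemistryParams(eta=1.0, eps=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
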