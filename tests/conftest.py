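import pytest

from rtcausal import PopulationSpec, named_fixture, random_population


@pytest.fixture(scope="session")
def worked_population() -> PopulationSpec:
    """Single-type population used throughout the narrative examples:
    always-exposed individuals whose disease follows the confounder and
    whose selection follows disease-under-exposure; P(C)=0.3, N=1000."""
    return PopulationSpec(1000, {(1, 6, 4): 1.0}, {(1, 6, 4): 0.3})


@pytest.fixture(scope="session")
def random_populations() -> list[PopulationSpec]:
    """A reusable batch of seeded random populations."""
    return [random_population(seed) for seed in range(50)]


@pytest.fixture(scope="session")
def confounded_population() -> PopulationSpec:
    return named_fixture("confounded", seed=1)


@pytest.fixture(scope="session")
def exchangeable_population() -> PopulationSpec:
    return named_fixture("et_dt", seed=1)
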