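import pytest

from natscreen.pairing import find_sa_pairs, resolve_complex
from natscreen.simulate import SimConfig, plant_census_genome, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (wing/leg/eye x 2 replicates), seed 0."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def study_pairs(study):
    return resolve_complex(find_sa_pairs(study.genes), study.genes)


@pytest.fixture(scope="session")
def census_genome():
    """Planted genome with 2 loci per simple configuration and 1 complex locus."""
    counts = {
        "internal": 2,
        "head_to_head": 2,
        "tail_to_tail": 2,
        "external": 2,
        "complex": 1,
    }
    return plant_census_genome(counts)
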