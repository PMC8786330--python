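import pytest
from hypothesis import HealthCheck, settings

from maglow import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    return syn.CommunitySpec(
        n_genomes=6,
        genome_length_range=(40_000, 60_000),
        total_bases=2.0e9,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    genomes, truth = syn.generate_genomes(small_spec)
    return genomes, truth


@pytest.fixture(scope="session")
def small_scaffolds(small_community):
    genomes, truth = small_community
    return syn.fragment_genomes(genomes, truth)


@pytest.fixture(scope="session")
def small_depth(small_community, small_scaffolds):
    genomes, truth = small_community
    return syn.simulate_depth(small_scaffolds, truth)
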