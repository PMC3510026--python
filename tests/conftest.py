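import pytest
from hypothesis import HealthCheck, settings

from lungeqtl import SimConfig, LungEqtlStudy
from lungeqtl.simulate import simulate_dataset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def small_config(**overrides) -> SimConfig:
    """A dataset small enough for second-scale fits but with every feature on."""
    base = dict(
        n_snps=300,
        n_probesets=80,
        samples_per_cohort=(120, 120, 120),
        network_genes=30,
        canonical_size=20,
        hub_children=6,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_results(small_dataset):
    study = LungEqtlStudy.from_dataset(small_dataset)
    return study.fit(seed=0)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 3 cohorts x 300, 2,000 SNPs, 500 probesets."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_results(default_dataset):
    return LungEqtlStudy.from_dataset(default_dataset).fit(seed=11)
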