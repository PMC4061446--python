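import pytest
from hypothesis import HealthCheck, settings

from blockvep.synthetic import FixtureSpec, generate_dataset, generate_fixture, worked_example

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Worked example: 7-hit MSA with hand-derived feature expectations."""
    we = worked_example()
    msa, part = we.build()
    return we, msa, part


@pytest.fixture(scope="session")
def default_fixture():
    """One protein at the package's default simulation conditions."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def small_dataset():
    """A light multi-protein dataset for CV plumbing tests."""
    spec = FixtureSpec(query_length=120, hits_per_category=(6,) * 5,
                       n_paralogs=2, seed=11)
    return generate_dataset(spec, n_proteins=8, variants_per_protein=6)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 50 proteins x 10 variants, seed 17."""
    return generate_dataset(FixtureSpec(seed=17), n_proteins=50,
                            variants_per_protein=10)
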