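import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def patterns():
    from bamboocad.sites import default_patterns

    return default_patterns()


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """A full synthetic input set shared by pipeline-level tests."""
    from bamboocad.simulate import generate_fixture_set

    outdir = tmp_path_factory.mktemp("synthetic")
    ledger = generate_fixture_set(outdir, seed=17)
    return outdir, ledger
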