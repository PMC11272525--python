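import pytest
from hypothesis import HealthCheck, settings

from psmcea import default_config, evaluate_base_case, run_psa

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def base_case(config):
    return evaluate_base_case(config)


@pytest.fixture(scope="session")
def psa_run(config):
    """One full-size probabilistic sensitivity analysis, shared by tests."""
    return run_psa(config, n_draws=5000, seed=314159)
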