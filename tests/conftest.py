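import pytest
from hypothesis import HealthCheck, settings

from invnet import PipelineConfig, SynthParams, generate_all, run_synthetic

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_params():
    """A small but complete study system shared across test modules."""
    return SynthParams(n_lakes=150, n_users=40, catches_per_user_mean=40.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return generate_all(small_params)


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return run_synthetic(PipelineConfig(seed=11), small_params)


@pytest.fixture(scope="session")
def default_params():
    """The default study scale: 500 lakes, 200 anglers, ~24k catches."""
    return SynthParams(seed=101)


@pytest.fixture(scope="session")
def default_bundle(default_params):
    return run_synthetic(PipelineConfig(seed=101), default_params)
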