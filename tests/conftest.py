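import pytest
from hypothesis import HealthCheck, settings

from simq import bundled_fixture_adapter, bundled_lexicon
from simq.synthetic import SynthConfig, generate_dataset

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lex():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def adapter():
    return bundled_fixture_adapter()


@pytest.fixture(scope="session")
def default_ds():
    """The benchmark dataset: 10 clusters x 3, 20 distractors, rate 0.8."""
    return generate_dataset(SynthConfig())


@pytest.fixture(scope="session")
def tiny_ds():
    return generate_dataset(SynthConfig(n_clusters=3, cluster_size=2, n_distractors=4))
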