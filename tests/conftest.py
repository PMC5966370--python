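import pytest
from hypothesis import HealthCheck, settings

from molsift.fingerprint import FingerprintParams
from molsift.fixtures import GeneratorConfig, random_corpus, toy_corpus
from molsift.index import build_index

settings.register_profile(
    "suite",
    max_examples=60,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_mols():
    return toy_corpus()


@pytest.fixture(scope="session")
def toy_index(toy_mols):
    return build_index(list(toy_mols.items()))


@pytest.fixture(scope="session")
def small_corpus():
    """100 random molecules, the shared screening testbed."""
    return random_corpus(GeneratorConfig(seed=7, n_molecules=100))


@pytest.fixture(scope="session")
def small_index(small_corpus):
    return build_index(small_corpus)


@pytest.fixture(scope="session")
def small_index_g3(small_corpus):
    return build_index(small_corpus, FingerprintParams(graph_size=3))
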