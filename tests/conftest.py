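import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from litsim.corpus import build_term_document_matrix
from litsim.synth import SynthConfig, generate_corpus, generate_grant_links

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_tdm():
    """6-document toy corpus with hand-enumerable term incidence."""
    docs = {
        "d1": ["apple", "apple", "berry"],
        "d2": ["apple", "cherry"],
        "d3": ["berry", "cherry", "cherry"],
        "d4": ["apple", "berry", "date"],
        "d5": ["cherry"],
        "d6": ["date", "elder"],
    }
    return docs, build_term_document_matrix(docs, min_df=1)


@pytest.fixture(scope="session")
def small_synth():
    """120-doc planted corpus used by the faster end-to-end tests."""
    config = SynthConfig(
        n_docs=120, n_clusters=4, vocab_size=600, n_grants=12,
        mean_articles_per_grant=5.0, seed=7,
    )
    records, truth = generate_corpus(config)
    links = generate_grant_links(truth, config)
    return config, records, truth, links


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
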