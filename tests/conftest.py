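import pytest

from ddicnn.preprocess import corpus_to_instances
from ddicnn.simulate import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A mixed-provenance synthetic corpus with bystanders and secondary pairs."""
    return generate_corpus(GeneratorConfig(n_documents=15), seed=42)


@pytest.fixture(scope="session")
def small_instances(small_corpus):
    instances, stats = corpus_to_instances(small_corpus)
    return instances


@pytest.fixture
def tiny_model_config():
    """Hyper-parameters small enough for seconds-scale training in tests."""
    return dict(me=16, md=4, n_filters=8, filter_sizes=(2, 3), epochs=5,
                batch_size=16, seed=0)
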