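import pytest
from hypothesis import settings

from picoextract.corpus_io import LabeledCorpus
from picoextract.pipeline import PipelineConfig, train_pipeline
from picoextract.semantic_tagger import default_bundle
from picoextract.synthetic_data import GeneratorSpec, generate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def small_corpus():
    """150 abstracts at strong signal; shared across test modules."""
    return generate_corpus(GeneratorSpec(n_abstracts=150, signal_strength=0.9, seed=11))


@pytest.fixture(scope="session")
def split_small(small_corpus):
    train = LabeledCorpus(small_corpus.abstracts[:100], provenance="train")
    test = LabeledCorpus(small_corpus.abstracts[100:], provenance="test")
    return train, test


@pytest.fixture(scope="session")
def small_model(split_small, bundle):
    """One CRF trained on the shared 100-abstract corpus (reused widely to
    keep the suite fast)."""
    train, _ = split_small
    return train_pipeline(train, PipelineConfig(), bundle)
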