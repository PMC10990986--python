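import warnings

import pytest

from aiscore import GeneratorConfig, TrainConfig, generate_corpus, train
from aiscore.training_prep import prepare_training_sentences


@pytest.fixture(scope="session")
def small_corpus():
    """30 synthetic annotated narratives (10 per dataset), fully punctuated."""
    return generate_corpus(GeneratorConfig(n_narratives=10, seed=1))


@pytest.fixture(scope="session")
def medium_corpus():
    """300 synthetic annotated narratives (100 per dataset)."""
    return generate_corpus(GeneratorConfig(n_narratives=100, seed=11))


@pytest.fixture(scope="session")
def trained_model(small_corpus):
    """Lightweight classifier trained on the small corpus."""
    labeled = prepare_training_sentences(small_corpus, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train(labeled, TrainConfig(seed=5))
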