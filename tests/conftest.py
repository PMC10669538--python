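import numpy as np
import pytest

import latentgrow as lg
from latentgrow.autoencoder import AutoencoderSpec, AutoencoderWeights

# Training conditions for the shared fixture autoencoder.  Chosen once (see
# docs/methods.md): a reduced-width topology with enough reconstruction noise
# for the mask to diffuse, trained on the standard texture corpus.
FIXTURE_TRAIN = dict(corpus_size=150, image_size=128, epochs=12, seed=0)


@pytest.fixture(scope="session")
def texture_corpus():
    return lg.generate_texture_corpus(
        FIXTURE_TRAIN["corpus_size"],
        size=(FIXTURE_TRAIN["image_size"],) * 2,
        seed=FIXTURE_TRAIN["seed"])


@pytest.fixture(scope="session")
def fixture_weights(texture_corpus):
    """Session-wide trained fixture autoencoder (trains once, ~1-2 min)."""
    return lg.train_fixture_autoencoder(
        texture_corpus, epochs=FIXTURE_TRAIN["epochs"],
        seed=FIXTURE_TRAIN["seed"])


@pytest.fixture(scope="session")
def random_weights():
    """Untrained (randomly initialised) reduced-width weights for shape and
    determinism contracts that do not need a trained model."""
    return AutoencoderWeights(AutoencoderSpec(3, 8), seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
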