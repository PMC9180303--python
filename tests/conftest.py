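import numpy as np
import pandas as pd
import pytest

from visrep import (
    FEATURE_NAMES,
    GeneratorConfig,
    PixelFeatureExtractor,
    ToyImageEmbedder,
    generate_corpus,
)

STUDY_SEED = 42
STUDY_N = 400


@pytest.fixture(scope="session")
def study_corpus():
    """The default synthetic study conditions: 400 photos, balanced classes."""
    config = GeneratorConfig(
        n_photos=STUDY_N, mix=0.5, image_size=(64, 64), seed=STUDY_SEED
    )
    return generate_corpus(config)


@pytest.fixture(scope="session")
def study_truth(study_corpus):
    return np.array([p.true_class for p in study_corpus])


@pytest.fixture(scope="session")
def study_pixel_features(study_corpus):
    extractor = PixelFeatureExtractor()
    table = pd.DataFrame(
        extractor.fit_transform([p.image for p in study_corpus]),
        index=[p.photo_id for p in study_corpus],
        columns=list(FEATURE_NAMES),
    )
    table.index.name = "photo_id"
    return table


@pytest.fixture(scope="session")
def study_embeddings(study_corpus):
    return ToyImageEmbedder().fit_transform([p.image for p in study_corpus])


@pytest.fixture()
def small_config():
    return GeneratorConfig(n_photos=20, mix=0.5, image_size=(32, 32), seed=7)


def uniform_image(r, g, b, size=(8, 8)):
    img = np.zeros((*size, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img
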