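import numpy as np
import pytest

from constellation.benchmark import DEFAULT_JITTER, planted_toy_stimulus
from constellation.generators import (NearestTemplateClassifier,
                                      ToyShapeGenerator)


@pytest.fixture(scope="session")
def toy_generator():
    return ToyShapeGenerator()


@pytest.fixture(scope="session")
def toy_classifier(toy_generator):
    return NearestTemplateClassifier.for_toy_generator(toy_generator)


@pytest.fixture(scope="session")
def planted_square():
    """Noise-free spacing-10 stimulus hiding a jittered toy square."""
    stim, z = planted_toy_stimulus("square", seed=0, spacing=10.0,
                                   noise_ratio=0.0, jitter=DEFAULT_JITTER)
    return stim, z


@pytest.fixture(scope="session")
def planted_circle_clean():
    """Noise-free spacing-10 stimulus from the canonical circle (no jitter)."""
    stim, z = planted_toy_stimulus("circle", seed=1, spacing=10.0,
                                   noise_ratio=0.0, jitter=0.0)
    return stim, z


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
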