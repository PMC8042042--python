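import numpy as np
import pytest
from hypothesis import settings

from crstress import synthdata

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def textured_image():
    """A seeded 320x256 textured 16-bit view for codec tests."""
    study = synthdata.generate_study(11, "malignant", 256, 320, 0.8)
    return study.views["LCC"].pixels


@pytest.fixture(scope="session")
def malignant_study():
    return synthdata.generate_study(7, "malignant", 256, 320, 0.8)


@pytest.fixture(scope="session")
def small_cohort():
    """60 studies at 160x128 — enough for pipeline smoke tests."""
    studies, manifest = synthdata.generate_cohort(
        3, 60, (0.5, 0.2, 0.3), width=128, height=160, separability=0.9)
    return studies, manifest


def rng_of(seed):
    return np.random.default_rng(seed)
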