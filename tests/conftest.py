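import pytest
from hypothesis import settings

# deterministic property tests: no wall-clock deadline, derandomized
settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from helpers import make_tiny_set
from kneeoa.data import AugmentPolicy, GradedImageSet, split_dataset
from kneeoa.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_synth() -> GradedImageSet:
    """A small generated set (140 images, 64px) with splits assigned."""
    cfg = SyntheticConfig(image_size=64, counts_per_grade=(40, 30, 35, 25, 10), seed=7)
    ds, _ = generate_dataset(cfg)
    return split_dataset(ds, (0.5, 0.2, 0.3), seed=7)


@pytest.fixture()
def null_policy() -> AugmentPolicy:
    return AugmentPolicy(
        horizontal_flip=False,
        rotation_range=0.0,
        width_shift_range=0.0,
        height_shift_range=0.0,
        zoom_range=0.0,
    )


@pytest.fixture()
def tiny_set_factory():
    return make_tiny_set
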