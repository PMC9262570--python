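import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rlmdpa import LabeledImageSet, NetworkArchitecture, SyntheticSpec, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_arch() -> NetworkArchitecture:
    """Small 16px architecture used throughout the desk-scale tests."""
    return NetworkArchitecture(
        input_size=16, conv_filters=(4, 3), fc_sizes=(8,), dropout_p=0.2
    )


@pytest.fixture(scope="session")
def separable_set() -> LabeledImageSet:
    """20 noise-free, fully separable 16px images (8 minority / 12 majority)."""
    return generate(
        SyntheticSpec(
            n_minority=8, n_majority=12, image_size=16,
            background_noise_sd=0.0, separability=1.0, seed=3,
        )
    )


@pytest.fixture(scope="session")
def imbalanced_set() -> LabeledImageSet:
    """10:1 imbalanced 16px set for reward-shaping experiments."""
    return generate(
        SyntheticSpec(
            n_minority=12, n_majority=120, image_size=16,
            background_noise_sd=0.02, separability=1.0, seed=11,
        )
    )
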