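import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitomorph.synthetic import (
    build_test_stack,
    default_test_specs,
    make_test_image_2d,
)


@pytest.fixture(scope="session")
def test_panel():
    """The default synthetic object panel: binary image + ground truth."""
    image, gt = make_test_image_2d(default_test_specs())
    return image, gt


@pytest.fixture(scope="session")
def test_stack(test_panel):
    """The 5-section unit-voxel layered stack built from the panel."""
    image, gt = test_panel
    stack, gt3 = build_test_stack(image, ground_truth=gt)
    return stack, gt3


def ball_mask(radius: float, shape=None) -> np.ndarray:
    from mitomorph.synthetic import binary_ball

    return binary_ball(radius, shape)
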