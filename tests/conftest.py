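import numpy as np
import pytest

from manoclass import classify, preprocess, synth_hrm
from manoclass.types import IRPClass, SwallowPattern


@pytest.fixture(scope="session")
def tiny_backbone():
    return classify.get_backbone(classify.BackboneSpec("tiny_test_cnn", seed=7))


@pytest.fixture(scope="session")
def normal_swallow():
    """One rendered normal swallow with normal IRP."""
    return synth_hrm.generate_swallow(SwallowPattern.NORMAL, IRPClass.NORMAL, seed=11)


def make_image(pixels: np.ndarray) -> preprocess.HRMImage:
    return preprocess.HRMImage(pixels.astype(np.uint8))


@pytest.fixture
def uniform_image():
    def _make(value: int, h: int = 40, w: int = 60) -> preprocess.HRMImage:
        return make_image(np.full((h, w, 3), value))

    return _make
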