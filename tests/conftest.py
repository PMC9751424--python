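import numpy as np
import pytest

from meibomorph.io_masks import GlandLabelMap, GrayImage, TarsusMask, label_map_from_array


def rect_label_map(h: int, w: int, pad: int = 2) -> GlandLabelMap:
    """A single filled h×w rectangle on a padded canvas."""
    arr = np.zeros((h + 2 * pad, w + 2 * pad), dtype=np.uint8)
    arr[pad : pad + h, pad : pad + w] = 1
    return label_map_from_array(arr)


def full_tarsus(shape) -> TarsusMask:
    return TarsusMask(np.ones(shape, dtype=bool))


def flat_image(shape, value: int = 100) -> GrayImage:
    return GrayImage(np.full(shape, value, dtype=np.uint8))


@pytest.fixture
def rng():
    return np.random.default_rng(20220112)
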