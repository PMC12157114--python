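import numpy as np
import pytest

from maskfuse import BinaryMask, MaskSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, h, w, p=0.5):
    return BinaryMask((rng.uniform(size=(h, w)) < p).astype(np.uint8))


def mask_from_rows(*rows):
    """Build a mask from strings of '0'/'1', e.g. mask_from_rows('01', '10')."""
    return BinaryMask(np.array([[int(c) for c in r] for r in rows], dtype=np.uint8))


@pytest.fixture
def tiny_series():
    a = mask_from_rows("1100", "0000", "0000", "0000")
    b = mask_from_rows("0110", "0110", "0000", "0000")
    return MaskSeries([a, b], series_id="tiny")
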