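import numpy as np
import pytest

from rectex.roi_io import SliceROI


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_roi(values, mask=None, sequence_type="transverse"):
    """SliceROI from a small array, relaxing the min-pixel rule for
    analytic micro-examples."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return SliceROI(values, np.asarray(mask), sequence_type, min_pixels=1)
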