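import numpy as np
import pytest

from fatmap.geometry import CenterOfRotation
from fatmap.io import FatFractionSlice, MuscleMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_slice_and_mask(rng):
    """Random 15x15 FI field with an irregular multifidus mask."""
    values = rng.uniform(0.0, 100.0, size=(15, 15))
    mask = rng.random((15, 15)) < 0.5
    mask[0, 0] = True  # guarantee non-empty
    fi = FatFractionSlice(values, subject_id="sub-001")
    return fi, MuscleMask(mask, muscle="multifidus")


@pytest.fixture
def cor_center():
    return CenterOfRotation((7.2, 6.8))
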