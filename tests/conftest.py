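import numpy as np
import pytest

from mmfpam import TransmissionMatrix, build_hadamard_pattern_set


@pytest.fixture
def toy_tm():
    """Single output mode with TM row [1, i, 1, 1] (N = 4)."""
    return TransmissionMatrix(
        np.array([[[1.0, 1.0j, 1.0, 1.0]]], dtype=complex),
        pixel_pitch_um=1.0, core_diameter_um=100.0)


@pytest.fixture
def had4():
    return build_hadamard_pattern_set(4)
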