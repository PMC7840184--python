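import numpy as np
import pytest
from scipy import ndimage

from tubuliflow.core_io import Roi
from tubuliflow.synthetic_data import PhantomParams, make_contracting_tubule


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def textured_image(rng):
    """Smooth random texture in [0, 1] with enough gradient for flow."""
    img = ndimage.gaussian_filter(rng.random((64, 64)), 2.0)
    return (img - img.min()) / np.ptp(img)


@pytest.fixture(scope="session")
def contracting_phantom():
    """Shared noise-free contracting-tubule phantom (4 px amplitude)."""
    params = PhantomParams(
        seed=7,
        contraction_amplitude_um=4.0,
        n_frames=30,
        onset_s=8.0,
        tau_rise_s=2.0,
        tau_decay_s=6.0,
    )
    return make_contracting_tubule(params)


@pytest.fixture
def full_roi():
    return Roi.from_mask("ROI 0", np.ones((64, 64), dtype=bool))
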