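import numpy as np
import pytest
from scipy import ndimage

from epiglim import AcquisitionGeometry, OpticalObject

BEAD = dict(d=1.9, n=1.605, n0=1.518, wavelength=0.490)
QUAD_EPS = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]


def smooth_phase_map(seed: int, shape=(64, 64), sigma=6.0, scale=2.0) -> np.ndarray:
    """Band-limited random phase map (radians), reproducible by seed."""
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma) * scale


@pytest.fixture
def geometry() -> AcquisitionGeometry:
    """Reflection geometry with the 0.3 um shear and dark-background bias."""
    return AcquisitionGeometry(shear_distance=0.3, geometry="reflection", wavelength=0.490)


@pytest.fixture
def smooth_object() -> OpticalObject:
    return OpticalObject(phase_map=smooth_phase_map(0), pixel_pitch=0.1)
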