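import numpy as np
import pytest

from mamseg.initcontour import manual_contour


@pytest.fixture(scope="session")
def disk_mask():
    """Filled disk of radius 40 centered in a 128x128 grid."""
    yy, xx = np.mgrid[0:128, 0:128]
    return np.hypot(xx - 64, yy - 64) <= 40


@pytest.fixture(scope="session")
def two_phase_disk():
    """Noise-free two-phase image: 0.9 inside a radius-35 disk, 0.2 outside."""
    yy, xx = np.mgrid[0:128, 0:128]
    r = np.hypot(xx - 64, yy - 64)
    truth = r < 35
    return np.where(truth, 0.9, 0.2), truth


@pytest.fixture(scope="session")
def loose_circle_init():
    """Circle of radius 50 around (64, 64): encloses the two-phase disk."""
    th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    return manual_contour(np.column_stack([64 + 50 * np.cos(th),
                                           64 + 50 * np.sin(th)]))


@pytest.fixture(scope="session")
def ellipse_blob():
    """Smooth elliptical blob (axes 50 and 30) for invariance checks."""
    yy, xx = np.mgrid[0:160, 0:160]
    return ((xx - 80) / 50.0) ** 2 + ((yy - 80) / 30.0) ** 2 <= 1.0
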