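import numpy as np
import pytest

from qams.chromio import Chromatogram
from qams.reference import six_sterol_calibrations, six_sterol_panel
from qams.synth import make_truth


@pytest.fixture(scope="session")
def panel():
    return six_sterol_panel()


@pytest.fixture(scope="session")
def published_curves():
    return six_sterol_calibrations()


@pytest.fixture()
def truth(panel, published_curves):
    return make_truth(panel, published_curves, seed=7)


@pytest.fixture()
def gaussian_trace():
    """Single noiseless Gaussian (amplitude 100 mAU, sigma 0.05 min, apex
    5 min) on a fine 0.001-min grid, plus its analytic area."""
    t = np.arange(0.0, 10.0, 0.001)
    sigma, amp, apex = 0.05, 100.0, 5.0
    y = amp * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
    area = amp * sigma * np.sqrt(2 * np.pi)
    return Chromatogram(t, y, 205.0), dict(sigma=sigma, amp=amp, apex=apex,
                                           area=area)
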