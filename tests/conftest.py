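import numpy as np
import pytest

from coilqa import synthetic as sy
from coilqa.elements import analyze_element_series


@pytest.fixture(scope="session")
def design():
    """Default acquisition geometry: 18 slices, 256 matrix, 135 mm phantom."""
    return sy.AcquisitionDesign()


@pytest.fixture(scope="session")
def small_design():
    """Cheap geometry for tests that only need a valid stack."""
    return sy.AcquisitionDesign(n_slices=4, matrix=96)


@pytest.fixture(scope="session")
def torso_combined(design):
    return sy.make_combined_series(
        design, sy.combined_signal_profile("torso"), sy.NoiseModel(), seed=101
    )


@pytest.fixture(scope="session")
def torso_elements(design):
    return sy.make_element_series(
        design, sy.default_elements("torso"), sy.NoiseModel(), seed=202
    )


@pytest.fixture(scope="session")
def torso_element_metrics(torso_elements):
    uncombined, sos, _ = torso_elements
    return analyze_element_series(uncombined, sos)


def draw_disc(shape, center, radius, value=100.0, background=0.0):
    """Noiseless disc fixture: pixel centers within ``radius`` of ``center``."""
    img = np.full(shape, background, dtype=np.float64)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = value
    return img
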