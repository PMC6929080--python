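import numpy as np
import pytest

from octlens.config import PipelineConfig
from octlens.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


def _phantom(**kw):
    spec = PhantomSpec(**kw)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def central_noiseless():
    return _phantom(scenario="central", speckle_sigma=0.0, contrast_decay=0.0)


@pytest.fixture(scope="session")
def central_default():
    return _phantom(scenario="central")


@pytest.fixture(scope="session")
def lateral_default():
    return _phantom(scenario="lateral")


@pytest.fixture(scope="session")
def extreme_noiseless():
    return _phantom(scenario="extreme", speckle_sigma=0.0, contrast_decay=0.0)


@pytest.fixture(scope="session")
def flat_noiseless():
    """Zero-curvature bands: lens [100, 108], cornea surface at 148."""
    return _phantom(scenario="central", speckle_sigma=0.0, contrast_decay=0.0,
                    lens_curvature=0.0, cornea_curvature=0.0, lens_apex_row=100.0)


def structure_tensor_orientation(pixels: np.ndarray) -> float:
    """Independent orientation oracle: dominant edge direction in degrees
    from the aggregated structure tensor (0 = horizontal edges)."""
    from skimage.feature import structure_tensor

    axx, axy, ayy = structure_tensor(pixels.astype(float), sigma=2.5)
    # dominant gradient direction; edges run perpendicular to it
    theta = 0.5 * np.arctan2(2 * axy.sum(), axx.sum() - ayy.sum())
    edge_deg = -np.degrees(theta)
    edge_deg = (edge_deg + 90.0) % 180.0 - 90.0
    return float(edge_deg)
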