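import numpy as np
import pytest

from brachydv.fileio import load_packaged_source
from brachydv.geometry import Contour
from brachydv.phantoms import PhantomConfig, generate_patient, thin_plan
from brachydv.tg43 import SourceDescription


@pytest.fixture(scope="session")
def source():
    return load_packaged_source("mHDR-v2")


@pytest.fixture(scope="session")
def flat_source():
    """Test source with g = 1 and F = 1 everywhere: dose rate reduces to the
    geometry-function ratio times the dose-rate constant."""
    return SourceDescription(
        model_id="flat",
        active_length_mm=3.5,
        dose_rate_constant=1.0,
        radial_r_cm=np.array([0.1, 1.0, 10.0]),
        radial_g=np.ones(3),
        aniso_r_cm=np.array([0.1, 1.0, 10.0]),
        aniso_theta_deg=np.array([0.0, 90.0, 180.0]),
        aniso_f=np.ones((3, 3)),
    )


@pytest.fixture(scope="session")
def cohort(source):
    """Three phantom patients at default study conditions."""
    cfg = PhantomConfig(seed=1, n_patients=3)
    return [generate_patient(cfg, i, source) for i in range(3)]


@pytest.fixture(scope="session")
def patient(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def reduced_plan(patient, source):
    """~50-dwell thinned plan rescaled to the planning aim."""
    return thin_plan(patient, source, 50)


def square_contour(z: float, half: float = 10.0, center=(0.0, 0.0)) -> Contour:
    cx, cy = center
    v = np.array(
        [[cx - half, cy - half], [cx + half, cy - half], [cx + half, cy + half], [cx - half, cy + half]]
    )
    return Contour(z, v)


def circle_contour(z: float, radius: float, n: int = 128, center=(0.0, 0.0)) -> Contour:
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(z, np.column_stack([center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi)]))
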