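import numpy as np
import pytest

from patdas import ScanGeometry, Sinogram, TransducerModel


@pytest.fixture(scope="session")
def sim_geometry():
    """Full-scale simulation geometry: 800 positions, 41 mm circle, 25 MHz."""
    return ScanGeometry(
        radius=41e-3,
        n_positions=800,
        angle_step=0.45,
        speed_of_sound=1500.0,
        sampling_frequency=25e6,
        n_samples=1500,
    )


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced geometry for fast unit tests (full circle, 16 positions)."""
    return ScanGeometry(
        radius=41e-3,
        n_positions=16,
        angle_step=22.5,
        speed_of_sound=1500.0,
        sampling_frequency=25e6,
        n_samples=1200,
    )


@pytest.fixture(scope="session")
def transducer():
    return TransducerModel(center_frequency=2.25e6, fractional_bandwidth=0.7)


@pytest.fixture
def random_sinogram(small_geometry):
    rng = np.random.default_rng(123)
    data = rng.standard_normal((small_geometry.n_positions, small_geometry.n_samples))
    return Sinogram(data, small_geometry)
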