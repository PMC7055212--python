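import numpy as np
import pytest

from betargs import CohortSpec, GeometrySpec, PhantomSpec, TransportConfig


@pytest.fixture
def fast_transport():
    """Small-n transport config for quick MC checks."""
    return TransportConfig(n_particles=20_000, rng_seed=11)


@pytest.fixture
def default_geometry():
    return GeometrySpec()


@pytest.fixture
def small_cohort_spec():
    return CohortSpec(n_patients=30, rng_seed=42)


@pytest.fixture
def clean_phantom_spec():
    """Noise-free, PSF-free phantom with a compact lesion (volume ~100 mm^3)."""
    return PhantomSpec(
        shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0),
        lesion_center=(40.0, 40.0, 40.0), lesion_radius=3.0,
        lesion_suv=12.0, background_suv=2.4,
        psf_fwhm=0.0, noise_scale=0.0, rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
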