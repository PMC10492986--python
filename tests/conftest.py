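import numpy as np
import pytest

from tricomp.synthetic import CohortSpec, PhantomSpec, WaveformSpec, generate_phantom


@pytest.fixture(scope="session")
def annulus_spec() -> PhantomSpec:
    """Circular body, radius 150 mm, SAT ring 30 mm, 1 slice, 3x3x10 mm voxels."""
    return PhantomSpec(
        slice_count=1,
        image_size=128,
        voxel_dims=(3.0, 3.0, 10.0),
        outer_semiaxes=(150.0, 150.0),
        sat_thickness=30.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def blob_spec() -> PhantomSpec:
    """Elliptical body with two VAT blobs."""
    return PhantomSpec(
        slice_count=3,
        image_size=128,
        outer_semiaxes=(150.0, 110.0),
        sat_thickness=30.0,
        vat_blobs=((20.0, 0.0, 25.0, 0.8), (-45.0, 15.0, 15.0, 0.75)),
        seed=11,
    )


@pytest.fixture(scope="session")
def blob_phantom(blob_spec):
    return generate_phantom(blob_spec)


@pytest.fixture(scope="session")
def annulus_phantom(annulus_spec):
    return generate_phantom(annulus_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_cohort_spec() -> CohortSpec:
    return CohortSpec(n=82, clinic_count=3, seed=5)


@pytest.fixture(scope="session")
def clean_waveform_spec() -> WaveformSpec:
    return WaveformSpec(true_pwv=4.0, reflection_onset=0.6, noise_sd=0.0, seed=0)
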