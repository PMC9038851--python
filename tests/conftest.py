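import numpy as np
import pytest

from fovsharp.ct_io import CTVolume, GridGeometry
from fovsharp.phantom import (
    Circle,
    Ellipse,
    PhantomSpec,
    ReconSpec,
    render_phantom,
    simulate_reconstruction,
)


@pytest.fixture(scope="session")
def clean_phantom_spec() -> PhantomSpec:
    """Deterministic two-bone, two-vessel leg cross-section."""
    return PhantomSpec(
        body=Ellipse((0.0, 0.0), (50.0, 45.0), hu=40.0),
        bones=(
            Circle((-15.0, 5.0), 10.0, hu=1200.0),
            Circle((12.0, -8.0), 7.0, hu=1200.0),
        ),
        vessels=(
            Circle((20.0, 15.0), 3.0, hu=350.0),
            Circle((-5.0, -20.0), 2.0, hu=350.0),
        ),
    )


@pytest.fixture(scope="session")
def phantom_truth(clean_phantom_spec) -> CTVolume:
    return render_phantom(clean_phantom_spec, 0.1, n_slices=4, slice_spacing=0.4)


@pytest.fixture(scope="session")
def recon_pair(phantom_truth):
    """Noiseless large/small FOV reconstructions of the clean phantom."""
    large = simulate_reconstruction(
        phantom_truth,
        ReconSpec(fov_diameter=423.0, n_slices=4, slice_spacing=0.4, noise_sd=0.0),
    )
    small = simulate_reconstruction(
        phantom_truth,
        ReconSpec(fov_diameter=220.0, n_slices=4, slice_spacing=0.4, noise_sd=0.0),
    )
    return large, small


@pytest.fixture(scope="session")
def noisy_recon(phantom_truth) -> CTVolume:
    return simulate_reconstruction(
        phantom_truth,
        ReconSpec(
            fov_diameter=220.0, n_slices=4, slice_spacing=0.4,
            noise_sd=10.0, seed=5,
        ),
    )


@pytest.fixture
def tiny_volume() -> CTVolume:
    rng = np.random.default_rng(7)
    geom = GridGeometry((8, 8), 2, (0.43, 0.43), 0.4, origin=(1.0, -2.0, 3.0))
    return CTVolume(rng.normal(0, 50, geom.shape), geom, identifier="tiny")
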