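import numpy as np
import pytest

from isletmorph import SceneSpec, render_scene


@pytest.fixture
def clean_sphere_scene():
    """One radius-4 µm sphere rendered without blur or noise (isotropic 0.5 µm)."""
    spec = SceneSpec(
        grid_shape=(40, 60, 60),
        voxel_size=(0.5, 0.5, 0.5),
        pancreas_center=(10.0, 15.0, 15.0),
        pancreas_semiaxes=(9.0, 13.0, 13.0),
        n_cells=1,
        psf_sigma=(0.0, 0.0, 0.0),
        noise_gaussian_sd=0.0,
        noise_poisson_scale=None,
        seed=0,
    )
    centers = np.array([[10.0, 15.0, 15.0]])
    red, green, truth = render_scene(spec, centers=centers, radii=4.0)
    return spec, red, green, truth


@pytest.fixture
def two_sphere_scene():
    """Spheres of r = 4 and 2.5 µm (≈268 and ≈65 µm³) in one pancreas blob."""
    spec = SceneSpec(
        grid_shape=(32, 80, 80),
        voxel_size=(1.0, 0.5, 0.5),
        pancreas_center=(16.0, 20.0, 20.0),
        pancreas_semiaxes=(12.0, 16.0, 16.0),
        n_cells=2,
        psf_sigma=(0.5, 0.3, 0.3),
        noise_gaussian_sd=1.0,
        noise_poisson_scale=2.0,
        seed=7,
    )
    centers = np.array([[16.0, 14.0, 20.0], [16.0, 28.0, 22.0]])
    red, green, truth = render_scene(spec, centers=centers, radii=np.array([4.0, 2.5]))
    return spec, red, green, truth
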