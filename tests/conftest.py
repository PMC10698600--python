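"""Shared fixtures: analytic phantoms at various grids."""

import numpy as np
import pytest

from neolung.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """Two spheres (r=20 and r=10 mm) on a 1 mm isotropic grid, noise-free."""
    spec = PhantomSpec(
        grid_shape=(70, 110, 70),
        spacing=(1, 1, 1),
        left_semi_axes=(20, 20, 20),
        right_semi_axes=(10, 10, 10),
        left_center=(35, 30, 35),
        right_center=(35, 85, 35),
        noise_sd=0.0,
        blur_sigma_mm=0.0,
        seed=1,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Two (30, 15, 15) mm ellipsoids (AP semi-axis 15, LR 15, CC 30) on a
    1 mm grid: elongation of the equivalent ellipsoid is exactly 2."""
    spec = PhantomSpec(
        grid_shape=(80, 110, 70),
        spacing=(1, 1, 1),
        left_semi_axes=(15, 15, 30),
        right_semi_axes=(15, 15, 30),
        left_center=(40, 25, 35),
        right_center=(40, 85, 35),
        noise_sd=0.0,
        blur_sigma_mm=0.0,
        seed=2,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def aniso_phantom():
    """Default-geometry phantom on the anisotropic acquisition grid."""
    spec = PhantomSpec(seed=3)
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
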