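import numpy as np
import pytest

from equivol import (RegistrationConfig, TriangulatedSurface, register,
                     register_normal)
from equivol.synthetic import concentric_spheres, icosphere


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere(1.0, 2)


@pytest.fixture(scope="session")
def small_sphere_pair():
    """Coarse concentric spheres r=1 -> 2 (icosahedron subdivided twice)."""
    return concentric_spheres(1.0, 2.0, 2)


@pytest.fixture(scope="session")
def small_constrained_registration(small_sphere_pair):
    """Normality-constrained registration on the coarse sphere pair,
    shared across laminar and validation tests."""
    s0, s1 = small_sphere_pair
    return register_normal(
        s0, s1, RegistrationConfig(discrepancy_weight=10.0,
                                   lbfgs_max_iterations=300))


@pytest.fixture(scope="session")
def small_unconstrained_registration():
    """Unconstrained registration of a mild sphere dilation (r=1 -> 1.5)."""
    s0, s1 = concentric_spheres(1.0, 1.5, 2)
    return register(s0, s1, RegistrationConfig(discrepancy_weight=10.0,
                                               lbfgs_max_iterations=300))


def planar_grid(n=9, side=2.0, z=0.0):
    """Regular triangulated square sheet in the z-plane, ccw from +z."""
    x = np.linspace(0.0, side, n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    verts = np.stack([X, Y, np.full_like(X, z)], axis=-1).reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = (i * n + j, (i + 1) * n + j,
                          (i + 1) * n + j + 1, i * n + j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return TriangulatedSurface(verts, np.asarray(faces), "grid")
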