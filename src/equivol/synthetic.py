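"""Deterministic synthetic surface pairs with analytic laminar ground truth.

Four phantom families cover the regimes the pipeline must handle:

* ``concentric_spheres`` - closed surfaces, pure radial flow; every laminar
  quantity has a closed form (thickness ``r1 - r0``, ``sigma = (r/r0)^2``,
  equal-volume shells at radius ``(r0^3 + eps (r1^3 - r0^3))^(1/3)``).
* ``ring_pair`` - an inner torus of constant tube radius and an outer one
  whose tube radius varies with the ring angle, giving a spatially varying
  thickness with a per-angle closed form.
* ``wavy_shell`` - an open folded sheet and its constant-distance offset:
  thin-slab cortex idealization with gyral crowns (negative inward
  curvature) and sulcal fundi (positive), for qualitative equivolume
  checks; deliberately open, a case volumetric level-set methods handle
  poorly.
* ``flat_slab`` - the degenerate analytic limit (``sigma = 1``,
  equivolumetric = equidistant).

All generators are deterministic given their parameters; optional vertex
jitter is applied only when a seed is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_core import TriangulatedSurface, vertex_normals
from .laminar import LaminarSystem

__all__ = [
    "PhantomSpec", "generate", "concentric_spheres", "ring_pair",
    "wavy_shell", "flat_slab", "icosphere",
    "radial_sphere_system", "normal_offset_system",
]


@dataclass
class PhantomSpec:
    """Recipe for a synthetic surface pair.

    ``params`` are forwarded to the generator named by ``kind``;
    ``resolution`` is the icosphere subdivision or grid density; ``seed``
    enables small deterministic vertex jitter (inner surface only).
    """

    kind: str
    params: dict = field(default_factory=dict)
    resolution: int = 3
    seed: int | None = None

    _KINDS = ("concentric_spheres", "ring_pair", "wavy_shell", "flat_slab")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; "
                             f"choose from {self._KINDS}")


def generate(spec: PhantomSpec):
    """Dispatch a :class:`PhantomSpec` to its generator; returns ``(S0, S1)``."""
    fn = {"concentric_spheres": concentric_spheres, "ring_pair": ring_pair,
          "wavy_shell": wavy_shell, "flat_slab": flat_slab}[spec.kind]
    s0, s1 = fn(resolution=spec.resolution, **spec.params)
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        edge = np.linalg.norm(
            s0.vertices[s0.faces[:, 0]] - s0.vertices[s0.faces[:, 1]], axis=1).mean()
        s0 = TriangulatedSurface(
            s0.vertices + 0.02 * edge * rng.standard_normal(s0.vertices.shape),
            s0.faces, s0.name)
    return s0, s1


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def icosphere(radius: float = 1.0, resolution: int = 3,
              name: str = "sphere") -> TriangulatedSurface:
    """An icosphere with outward winding (trimesh subdivision scheme)."""
    ico = trimesh.creation.icosphere(subdivisions=resolution, radius=radius)
    return TriangulatedSurface(np.asarray(ico.vertices), np.asarray(ico.faces),
                               name=name)


def concentric_spheres(r0: float = 1.0, r1: float = 2.0, resolution: int = 3):
    """Two concentric icospheres sharing topology, ``0 < r0 < r1``."""
    if not 0 < r0 < r1:
        raise ValueError(f"radii must satisfy 0 < r0 < r1, got {r0}, {r1}")
    inner = icosphere(1.0, resolution)
    return (TriangulatedSurface(r0 * inner.vertices, inner.faces, "inner_sphere"),
            TriangulatedSurface(r1 * inner.vertices, inner.faces, "outer_sphere"))


def _torus(ring_radius: float, tube_radius, n_ring: int, n_tube: int,
           name: str) -> TriangulatedSurface:
    """Torus-like tube; ``tube_radius`` is a scalar or a function of the
    ring angle phi.  Winding gives outward normals (away from the center
    circle)."""
    phi = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
    theta = np.linspace(0.0, 2 * np.pi, n_tube, endpoint=False)
    r = np.full_like(phi, tube_radius) if np.isscalar(tube_radius) \
        else np.asarray([tube_radius(p) for p in phi], dtype=np.float64)
    if (r <= 0).any():
        raise ValueError("tube radius profile must be positive")
    if (r >= ring_radius).any():
        raise ValueError("tube radius reaches the ring axis (self-intersection)")
    P, Th = np.meshgrid(phi, theta, indexing="ij")
    R = r[:, None]
    er = np.stack([np.cos(P), np.sin(P), np.zeros_like(P)], axis=-1)
    ez = np.array([0.0, 0.0, 1.0])
    pts = (ring_radius * er
           + R[..., None] * (np.cos(Th)[..., None] * er + np.sin(Th)[..., None] * ez))
    verts = pts.reshape(-1, 3)

    def vid(i, j):
        return (i % n_ring) * n_tube + (j % n_tube)

    faces = []
    for i in range(n_ring):
        for j in range(n_tube):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return TriangulatedSurface(verts, np.asarray(faces), name)


def ring_pair(tube_r0: float = 0.15, tube_r1_profile=None,
              ring_radius: float = 1.0, resolution: int = 32, slab: bool = False):
    """Inner tube of constant cross-section radius and outer tube whose
    radius varies with the ring angle (default: single-harmonic cosine
    ``0.3 + 0.1 cos(phi)``), both closed tori around the same center circle.

    Radial thickness at ring angle ``phi`` is ``profile(phi) - tube_r0`` in
    closed form.  ``slab=True`` instead extrudes the two ring cross-sections
    into a thin flat annular band pair (an open-surface variant of the same
    figure-of-revolution geometry).
    """
    if tube_r1_profile is None:
        tube_r1_profile = lambda p: 0.3 + 0.1 * np.cos(p)
    prof_min = min(tube_r1_profile(p) for p in np.linspace(0, 2 * np.pi, 256))
    if prof_min <= tube_r0:
        raise ValueError(
            f"outer profile (min {prof_min:.3g}) must exceed tube_r0={tube_r0}")
    if slab:
        return (_annulus_band(ring_radius, tube_r0, resolution, "inner_ring_slab"),
                _annulus_band(ring_radius, tube_r1_profile, resolution,
                              "outer_ring_slab"))
    n_tube = max(8, resolution // 2)
    return (_torus(ring_radius, tube_r0, resolution, n_tube, "inner_ring"),
            _torus(ring_radius, tube_r1_profile, resolution, n_tube, "outer_ring"))


def _annulus_band(ring_radius: float, offset, n_ring: int,
                  name: str) -> TriangulatedSurface:
    """Flat band in the xy-plane at radius ``ring_radius +/- offset(phi)``,
    triangulated as an open strip (thin-slab extrusion of a ring)."""
    phi = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
    off = np.full_like(phi, offset) if np.isscalar(offset) \
        else np.asarray([offset(p) for p in phi])
    inner_r = ring_radius - off
    outer_r = ring_radius + off
    er = np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1)
    verts = np.concatenate([inner_r[:, None] * er, outer_r[:, None] * er])
    faces = []
    for i in range(n_ring):
        a, b = i, (i + 1) % n_ring
        c, d = n_ring + (i + 1) % n_ring, n_ring + i
        faces.append([a, b, c])
        faces.append([a, c, d])
    return TriangulatedSurface(verts, np.asarray(faces), name)


def _grid_sheet(nx: int, ny: int, side: float, height_fn, normal_fn):
    x = np.linspace(0.0, side, nx)
    y = np.linspace(0.0, side, ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    Z = height_fn(X)
    verts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    normals = normal_fn(X).reshape(-1, 3)

    def vid(i, j):
        return i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return verts, normals, np.asarray(faces)


def wavy_shell(amplitude: float = 0.15, frequency: float = 0.5,
               separation: float = 0.4, side: float = 2.0, resolution: int = 33):
    """Open folded sheet ``z = A sin(2 pi f x)`` over a square patch, and
    its offset along the inner analytic normals by ``separation``.

    Crowns (local maxima, bulging toward the outer sheet) have negative
    inward curvature; fundi positive.  Raises when the offset distance
    exceeds the fold's radius of curvature (self-intersecting pair).
    """
    if amplitude < 0 or separation <= 0:
        raise ValueError("need amplitude >= 0 and separation > 0")
    # curvature of A sin(2 pi f x): max |z''| = A (2 pi f)^2 (f in cycles per unit x)
    kmax = amplitude * (2 * np.pi * frequency) ** 2
    if kmax * separation >= 1.0:
        raise ValueError(
            f"offset {separation} exceeds the minimal radius of curvature "
            f"{1.0 / kmax:.3g}: the shell self-intersects")

    w = 2 * np.pi * frequency

    def height(X):
        return amplitude * np.sin(w * X)

    def normal(X):
        gp = amplitude * w * np.cos(w * X)
        denom = np.sqrt(1.0 + gp ** 2)
        return np.stack([-gp / denom, np.zeros_like(X), 1.0 / denom], axis=-1)

    n = max(resolution, 4)
    verts, normals, faces = _grid_sheet(n, n, side, height, normal)
    inner = TriangulatedSurface(verts, faces, "inner_sheet")
    outer = TriangulatedSurface(verts + separation * normals, faces, "outer_sheet")
    return inner, outer


def flat_slab(side: float = 2.0, height: float = 0.5, resolution: int = 17):
    """Planar square sheets at ``z = 0`` and ``z = height`` (flat limit)."""
    if side <= 0 or height <= 0:
        raise ValueError("side and height must be positive")
    n = max(resolution, 2)
    verts, _, faces = _grid_sheet(
        n, n, side, lambda X: np.zeros_like(X),
        lambda X: np.stack([np.zeros_like(X), np.zeros_like(X),
                            np.ones_like(X)], axis=-1))
    lower = TriangulatedSurface(verts, faces, "lower_slab")
    upper = TriangulatedSurface(verts + [0.0, 0.0, height], faces, "upper_slab")
    return lower, upper


# ---------------------------------------------------------------------------
# analytic laminar systems (closed-form flows for validation)
# ---------------------------------------------------------------------------

def radial_sphere_system(r0: float = 1.0, r1: float = 2.0, resolution: int = 3,
                         n_times: int = 21) -> LaminarSystem:
    """The exact radial flow ``psi(t, x) = x (r0 + t (r1 - r0)) / r0`` on an
    icosphere, with exact nodal velocities: unit-speed (per unit t) normal
    inflation scaled by ``r1 - r0``."""
    sphere = icosphere(1.0, resolution)
    times = np.linspace(0.0, 1.0, n_times)
    radii = r0 + times * (r1 - r0)
    positions = radii[:, None, None] * sphere.vertices[None, :, :]
    velocities = np.broadcast_to(
        (r1 - r0) * sphere.vertices[None, :, :], positions.shape).copy()
    return LaminarSystem(times, positions, sphere.faces, velocities)


def normal_offset_system(surface: TriangulatedSurface, distance: float,
                         n_times: int = 11,
                         normals: np.ndarray | None = None) -> LaminarSystem:
    """Constant-speed offset flow ``psi(t, x) = x + t d n(x)`` along fixed
    (analytic or mesh) inner-surface normals: the equidistant laminar
    system, the natural baseline against the equivolumetric one."""
    if normals is None:
        normals = vertex_normals(surface)
    times = np.linspace(0.0, 1.0, n_times)
    positions = (surface.vertices[None, :, :]
                 + times[:, None, None] * distance * normals[None, :, :])
    velocities = np.broadcast_to(distance * normals[None, :, :],
                                 positions.shape).copy()
    return LaminarSystem(times, positions, surface.faces, velocities)
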