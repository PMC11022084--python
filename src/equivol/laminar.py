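"""Laminar coordinate systems: streamlines, layers, depth, and the
equivolumetric (Bok) reparametrization.

A laminar coordinate system is a family of surfaces ("layers") sweeping the
space between an inner surface ``S0`` and an outer surface ``S1``, together
with the curves ("streamlines") traced by each material vertex - the
discrete analogue of cortical columns.  Given such a system this module
computes, per streamline,

* the thickness ``theta`` (streamline length);
* the surface Jacobian ``sigma(t)`` (one-ring area ratio, or the exact
  cofactor-transport alternative along the analytic flow);
* the equivolumetric depth ``gamma(t) = int_0^t (w . n) sigma du``, the
  volume swept per unit reference area;
* the volume fraction ``tau = gamma / gamma(1)`` used as a space-dependent
  time change.

Resampling the layers at fixed ``tau``-levels makes them equivolumetric in
the localized sense: between any two levels, every infinitesimal tube
contains the same fraction of its total volume.  Streamlines are unchanged
by the operation; their normality to the layers, if present, is generally
lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelSpec, PointWeights, kernel_field, kernel_field_jacobian
from .mesh_core import TriangulatedSurface, one_ring_area, vertex_normals
from .registration import RegistrationResult

__all__ = [
    "LaminarSystem", "build_laminar_system", "thickness",
    "surface_jacobian", "surface_jacobian_transport", "equivol_depth",
    "time_change", "extract_equivol_layer", "reparametrize",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class LaminarSystem:
    """Discrete laminar coordinates: per-time vertex positions sharing the
    topology of ``S0``, with per-time velocities and layer normals.

    ``normals`` are unit vertex normals of each time slice, globally
    oriented so that ``n . w >= 0`` at ``t = 0`` (the flow direction) and
    following continuously in ``t`` through the shared winding.
    """

    times: np.ndarray          # (M,), 0 = inner surface, 1 = outer surface
    positions: np.ndarray      # (M, N, 3)
    faces: np.ndarray          # (F, 3) shared topology
    velocities: np.ndarray     # (M, N, 3), d(psi)/dt at the nodes
    normals: np.ndarray = None # (M, N, 3), filled by __post_init__ if None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        m, n, _ = self.positions.shape
        if self.times.shape != (m,) or self.velocities.shape != (m, n, 3):
            raise ValueError("inconsistent laminar system shapes")
        if self.normals is None:
            self.normals = self._oriented_normals()

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_streamlines(self) -> int:
        return self.positions.shape[1]

    def surface_at(self, index: int, name: str = "") -> TriangulatedSurface:
        return TriangulatedSurface(self.positions[index], self.faces, name)

    def _oriented_normals(self) -> np.ndarray:
        normals = np.array([
            vertex_normals(self.surface_at(j)) for j in range(self.n_times)])
        # orient along the flow at t=0; winding keeps the sign continuous in t
        sign = np.sum(normals[0] * self.velocities[0])
        if sign < 0:
            normals = -normals
        return normals

    @classmethod
    def from_positions(cls, times, positions, faces, velocities=None
                       ) -> "LaminarSystem":
        """Build a system from explicit layer positions (e.g. an analytic
        flow); velocities default to centered finite differences in t."""
        times = np.asarray(times, dtype=np.float64)
        positions = np.asarray(positions, dtype=np.float64)
        if velocities is None:
            velocities = np.gradient(positions, times, axis=0)
        return cls(times, positions, np.asarray(faces), velocities)

    def validate(self) -> "LaminarSystem":
        """Check every slice is a valid surface; report the failing time index."""
        for j in range(self.n_times):
            try:
                self.surface_at(j).validate(check_winding=(j == 0))
            except Exception as exc:
                raise ValueError(f"degenerate layer at time index {j} "
                                 f"(t={self.times[j]:.3f}): {exc}") from exc
        return self

    def embedding_violations(self) -> int:
        """Cheap fold-over check: count faces whose normal reverses between
        consecutive layers (a necessary symptom of a non-embedded sweep)."""
        count = 0
        prev = None
        for j in range(self.n_times):
            tri = self.positions[j][self.faces]
            nf = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            if prev is not None:
                count += int(np.sum(np.einsum("ij,ij->i", nf, prev) <= 0))
            prev = nf
        return count


# ---------------------------------------------------------------------------
# construction from a registration
# ---------------------------------------------------------------------------

def build_laminar_system(result: RegistrationResult, refinement: int = 1,
                         integrator: str = "euler") -> LaminarSystem:
    """Streamlines and layers from a registration flow.

    With ``refinement == 1`` and the Euler integrator the layer positions
    are exactly the stored vertex trajectories.  Larger refinements (or
    ``integrator='rk4'``) re-integrate the streamline ODE on a grid with
    ``refinement`` sub-steps per registration step, using the analytic
    kernel expansion of the velocity; one velocity field per registration
    step, frozen at the step's stored support configuration.
    """
    T = result.time_steps
    h = 1.0 / T
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    dt = h / refinement
    q = result.trajectories[0].copy()
    positions = [q.copy()]
    velocities = [result.velocity(0, q)]
    for t in range(T):
        pw = PointWeights(result.trajectories[t], result.momentum[t])
        f = lambda x: kernel_field(result.flow_kernel, pw, x)
        for _ in range(refinement):
            if integrator == "euler":
                q = q + dt * f(q)
            elif integrator == "rk4":
                k1 = f(q)
                k2 = f(q + 0.5 * dt * k1)
                k3 = f(q + 0.5 * dt * k2)
                k4 = f(q + dt * k3)
                q = q + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            else:
                raise ValueError(f"unknown integrator {integrator!r}")
            positions.append(q.copy())
            # nodal velocity from the analytic field of the step that owns
            # this node (the last node of each step uses that step's field)
            velocities.append(f(q))
    times = np.array([j * dt for j in range(T * refinement + 1)])
    system = LaminarSystem(times, np.array(positions), result.faces.copy(),
                           np.array(velocities))
    return system.validate()


# ---------------------------------------------------------------------------
# per-streamline fields
# ---------------------------------------------------------------------------

def thickness(system: LaminarSystem) -> np.ndarray:
    """Streamline length per vertex: the polyline length over the time grid."""
    seg = np.diff(system.positions, axis=0)
    return np.linalg.norm(seg, axis=2).sum(axis=0)


def surface_jacobian(system: LaminarSystem) -> np.ndarray:
    """One-ring area ratio ``sigma(t, k) = a(t, k) / a(0, k)``; ``sigma(0) = 1``."""
    areas = np.array([one_ring_area(system.surface_at(j))
                      for j in range(system.n_times)])
    a0 = areas[0]
    if (a0 <= 0).any():
        raise ValueError("zero one-ring area on the inner surface")
    return areas / a0


def surface_jacobian_transport(result: RegistrationResult,
                               refinement: int = 1,
                               integrator: str = "rk4",
                               normals0: np.ndarray | None = None,
                               debug_ode: bool = False) -> np.ndarray:
    """Surface Jacobian from the cofactor transport of the analytic flow.

    Writes ``sigma = det(dphi) |dphi^-T nu0|`` and transports the vector
    ``zeta = det(dphi) dphi^-T nu0`` along each streamline with

        d zeta / dt = div(v) zeta - (dv)^T zeta,

    integrated (RK4 by default) with the exact kernel-expansion Jacobian of
    ``v``; then ``sigma(t, k) = |zeta(t, k)|`` since ``|nu0| = 1``.

    ``debug_ode=True`` selects a deliberately simplified variant
    ``d zeta/dt = div(v) - (dv) zeta`` (no zeta factor on the divergence
    term, no transpose), kept only for debugging comparisons; it is
    dimensionally inconsistent and does not reproduce the one-ring
    estimate.
    """
    T = result.time_steps
    dt = 1.0 / (T * refinement)
    q = result.trajectories[0].copy()
    if normals0 is None:
        normals0 = vertex_normals(result.surface_at(0))
    zeta = normals0.copy()
    sigma = [np.linalg.norm(zeta, axis=1)]

    def rhs(t_index, y, z):
        pw = PointWeights(result.trajectories[t_index], result.momentum[t_index])
        v = kernel_field(result.flow_kernel, pw, y)
        J = kernel_field_jacobian(result.flow_kernel, pw, y)
        div = np.trace(J, axis1=1, axis2=2)
        if debug_ode:
            dz = div[:, None] - np.einsum("nij,nj->ni", J, z)
        else:
            dz = div[:, None] * z - np.einsum("nji,nj->ni", J, z)
        return v, dz

    for t in range(T):
        for _ in range(refinement):
            if integrator == "euler":
                v1, z1 = rhs(t, q, zeta)
                q = q + dt * v1
                zeta = zeta + dt * z1
            else:
                v1, z1 = rhs(t, q, zeta)
                v2, z2 = rhs(t, q + 0.5 * dt * v1, zeta + 0.5 * dt * z1)
                v3, z3 = rhs(t, q + 0.5 * dt * v2, zeta + 0.5 * dt * z2)
                v4, z4 = rhs(t, q + dt * v3, zeta + dt * z3)
                q = q + dt / 6.0 * (v1 + 2 * v2 + 2 * v3 + v4)
                zeta = zeta + dt / 6.0 * (z1 + 2 * z2 + 2 * z3 + z4)
            if not np.isfinite(zeta).all():
                raise FloatingPointError("zeta transport diverged")
            sigma.append(np.linalg.norm(zeta, axis=1))
    return np.array(sigma)


def equivol_depth(system: LaminarSystem, sigma: np.ndarray,
                  quadrature: str = "segment") -> np.ndarray:
    """Equivolumetric depth ``gamma(t, k)``: trapezoidal quadrature of
    ``(w . n) sigma`` along each streamline, with ``gamma(0, .) = 0``.

    Units: volume per unit inner-surface area, i.e. a length (mm).

    The default ``segment`` quadrature realizes ``w dt`` exactly as the
    polyline segment displacement and averages the endpoint values of
    ``n sigma`` - trapezoidal in the smooth factor, exact in the
    displacement, and well defined for resampled systems whose nodal
    velocities are only known by finite differences.  ``quadrature='nodal'``
    is the plain trapezoid on the nodal values ``(w . n) sigma`` using the
    system's stored velocities.
    """
    sigma = np.asarray(sigma, dtype=np.float64)
    if sigma.shape != system.positions.shape[:2]:
        raise ValueError(f"sigma shape {sigma.shape} does not match the "
                         f"system grid {system.positions.shape[:2]}")
    if quadrature == "nodal":
        integrand = np.einsum("mnj,mnj->mn",
                              system.velocities, system.normals) * sigma
        dt = np.diff(system.times)[:, None]
        increments = 0.5 * (integrand[1:] + integrand[:-1]) * dt
    elif quadrature == "segment":
        dpsi = np.diff(system.positions, axis=0)
        increments = 0.5 * (
            np.einsum("mnj,mnj->mn", dpsi, system.normals[:-1]) * sigma[:-1]
            + np.einsum("mnj,mnj->mn", dpsi, system.normals[1:]) * sigma[1:])
    else:
        raise ValueError(f"unknown quadrature {quadrature!r}")
    return np.vstack([np.zeros(system.n_streamlines), np.cumsum(increments, axis=0)])


def time_change(gamma: np.ndarray):
    """Per-streamline volume fraction: ``c0 = gamma(1, .)``,
    ``tau(t, k) = gamma(t, k) / c0(k)``.

    ``tau`` runs from 0 to 1 exactly and is nondecreasing whenever the flow
    does not backtrack through the layers.  A non-positive ``c0`` (total
    swept volume <= 0) indicates a backtracking streamline and is an error
    naming the vertex.
    """
    gamma = np.asarray(gamma, dtype=np.float64)
    c0 = gamma[-1].copy()
    if (c0 <= 0).any():
        bad = int(np.argmin(c0))
        raise ValueError(
            f"non-positive equivolumetric thickness c0={c0[bad]:.3g} at "
            f"vertex {bad}: the flow backtracks through the layers")
    return c0, gamma / c0


def _check_monotone(tau: np.ndarray, tol: float = 1e-9):
    dec = np.diff(tau, axis=0) < -tol
    if dec.any():
        bad = np.unique(np.where(dec)[1])
        raise ValueError(
            f"tau decreases along {len(bad)} streamline(s), first at vertex "
            f"{bad[0]}: the flow backtracks through the layers")


def extract_equivol_layer(system: LaminarSystem, tau: np.ndarray,
                          level: float) -> TriangulatedSurface:
    """The layer at volume fraction ``level``: per streamline, invert
    ``tau(t) = level`` piecewise-linearly and interpolate the positions.

    ``level=0`` returns the inner surface, ``level=1`` the final layer,
    both vertex-identical.  A stalled segment (zero ``tau`` increment) maps
    the level to its left endpoint.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level must be in [0, 1], got {level}")
    tau = np.asarray(tau, dtype=np.float64)
    _check_monotone(tau)
    if level == 0.0:
        return system.surface_at(0, name="layer_0")
    if level == 1.0:
        return system.surface_at(system.n_times - 1, name="layer_1")
    # first node with tau >= level, per streamline
    j_hi = np.argmax(tau >= level, axis=0)
    j_hi = np.maximum(j_hi, 1)
    cols = np.arange(system.n_streamlines)
    t_lo = tau[j_hi - 1, cols]
    t_hi = tau[j_hi, cols]
    denom = t_hi - t_lo
    frac = np.where(denom > 0, (level - t_lo) / np.where(denom > 0, denom, 1.0), 0.0)
    p_lo = system.positions[j_hi - 1, cols]
    p_hi = system.positions[j_hi, cols]
    vertices = p_lo + frac[:, None] * (p_hi - p_lo)
    return TriangulatedSurface(vertices, system.faces, name=f"layer_{level:g}")


def reparametrize(system: LaminarSystem, tau: np.ndarray,
                  levels: int | np.ndarray = None) -> LaminarSystem:
    """Resample every streamline at fixed ``tau``-levels.

    The streamlines, as point sets, are unchanged; the layers become
    equivolumetric in the localized sense (equal per-tube volume fraction
    between consecutive levels).  Normality of streamlines to the new
    layers, if it held before, is generally lost.

    ``levels`` is either a count ``L`` (uniform levels ``0, 1/L, ..., 1``)
    or an explicit increasing array starting at 0 and ending at 1; default
    is the size of the input grid.
    """
    if levels is None:
        levels = system.n_times - 1
    if np.isscalar(levels):
        levels = np.linspace(0.0, 1.0, int(levels) + 1)
    levels = np.asarray(levels, dtype=np.float64)
    if levels[0] != 0.0 or levels[-1] != 1.0 or (np.diff(levels) <= 0).any():
        raise ValueError("levels must increase from 0 to 1")
    layers = [extract_equivol_layer(system, tau, lv).vertices for lv in levels]
    return LaminarSystem.from_positions(levels, np.array(layers), system.faces)
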