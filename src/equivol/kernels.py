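"""Matrix-valued reproducing kernels for the deformation space.

The registration velocity fields live in a reproducing-kernel Hilbert space
``V`` whose kernel is a scalar radial kernel times the 3x3 identity,

    K(x, y) = k(|x - y|^2) I_3,

with ``k`` either a single Gaussian or a normalized sum of Gaussians
(a crude multiscale / Matern-like profile).  The key practical property is
that the optimal velocity field is a finite kernel expansion over the moving
vertices, so the field and its space derivatives are known in closed form
everywhere - no grid, no interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "PointWeights", "kernel_matrix", "kernel_field",
           "kernel_field_jacobian", "rkhs_energy"]

#: direct O(N^2) kernel sums get slow above this many support points
N_POINTS_WARN = 5000


@dataclass(frozen=True)
class KernelSpec:
    """A radial kernel family and width.

    Parameters
    ----------
    width
        Kernel width(s) in mm; a scalar for ``family='gaussian'``, a tuple
        for the sum-of-Gaussians family.
    family
        ``'gaussian'`` or ``'sum_gaussian'``.
    weights
        Mixture weights for the sum family (normalized to sum to 1 so that
        ``k(0) = 1`` always holds).
    """

    width: float | tuple[float, ...]
    family: str = "gaussian"
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        widths = np.atleast_1d(np.asarray(self.width, dtype=np.float64))
        if (widths <= 0).any():
            raise ValueError(f"kernel width must be positive, got {self.width}")
        if self.family not in ("gaussian", "sum_gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")

    @property
    def widths(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.width, dtype=np.float64))

    @property
    def mix(self) -> np.ndarray:
        if self.weights is None:
            w = np.ones(len(self.widths))
        else:
            w = np.asarray(self.weights, dtype=np.float64)
            if len(w) != len(self.widths):
                raise ValueError("weights / widths length mismatch")
        return w / w.sum()

    # -- scalar profile k(r^2) and derivative dk/d(r^2) ---------------------
    def k(self, r2: np.ndarray) -> np.ndarray:
        out = np.zeros_like(r2)
        for c, s in zip(self.mix, self.widths):
            out += c * np.exp(-r2 / (2.0 * s * s))
        return out

    def dk(self, r2: np.ndarray) -> np.ndarray:
        """d k / d(r^2); for a Gaussian this is ``-k / (2 s^2)`` per term."""
        out = np.zeros_like(r2)
        for c, s in zip(self.mix, self.widths):
            out += -c / (2.0 * s * s) * np.exp(-r2 / (2.0 * s * s))
        return out


@dataclass
class PointWeights:
    """Support points with attached momentum vectors (``q(t, .)``, ``alpha(t, .)``)."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=np.float64))
        if self.points.shape != self.weights.shape or self.points.shape[1] != 3:
            raise ValueError(
                f"points {self.points.shape} and weights {self.weights.shape} "
                "must both be (N, 3)")


def _sq_dists(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x[:, None, :] - y[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def kernel_matrix(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Scalar kernel Gram block ``k(|x_i - y_j|^2)`` of shape (len(x), len(y))."""
    if max(len(x), len(y)) > N_POINTS_WARN:
        warnings.warn(
            f"direct kernel sum over {max(len(x), len(y))} points; "
            "this implementation is O(N^2)", RuntimeWarning, stacklevel=2)
    return spec.k(_sq_dists(x, y))


def kernel_field(spec: KernelSpec, pw: PointWeights,
                 queries: np.ndarray) -> np.ndarray:
    """Evaluate ``v(x) = sum_l K(x, q_l) alpha_l`` at the query points."""
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    return kernel_matrix(spec, queries, pw.points) @ pw.weights


def kernel_field_jacobian(spec: KernelSpec, pw: PointWeights,
                          queries: np.ndarray) -> np.ndarray:
    """Exact space derivative ``dv/dx`` as one 3x3 matrix per query point.

    For the radial kernel ``k(|x - q|^2)``,
    ``d v_i / d x_j = sum_l alpha_l[i] * 2 k'(r^2) (x - q_l)[j]``.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    d = queries[:, None, :] - pw.points[None, :, :]          # (M, N, 3)
    g = 2.0 * spec.dk(np.einsum("ijk,ijk->ij", d, d))        # (M, N)
    return np.einsum("mn,ni,mnj->mij", g, pw.weights, d)


def rkhs_energy(spec: KernelSpec, pw: PointWeights) -> float:
    """Quadratic RKHS norm ``sum_{k,l} alpha_k . K(q_k, q_l) alpha_l`` (>= 0)."""
    G = kernel_matrix(spec, pw.points, pw.points)
    return float(np.einsum("ij,ik,jk->", G, pw.weights, pw.weights))
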