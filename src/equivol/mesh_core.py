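"""Triangulated surfaces: data model, standard-format I/O, discrete operators.

The laminar pipeline manipulates oriented triangle meshes representing the
inner (grey-white) and outer (pial) boundaries of a cortical region, and the
intermediate layers produced by the registration flow.  Everything downstream
(curvature, one-ring areas, tangential divergence) is defined on this data
model.

Conventions
-----------
* vertices are ``(N, 3)`` float64 arrays, units mm by convention;
* faces are ``(F, 3)`` int arrays of 0-based vertex indices with
  counterclockwise winding defining the outward normal;
* meshes may be closed (sphere-like) or open with boundary (disk-like);
* the mean-curvature sign convention is the one natural for an outward
  normal field: a sphere of radius ``r`` has ``H = -1/r``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import trimesh

__all__ = [
    "TriangulatedSurface",
    "VertexScalarField",
    "VertexVectorField",
    "read_surface",
    "write_surface",
    "vertex_normals",
    "one_ring_area",
    "mean_curvature",
    "surface_divergence",
    "face_areas",
    "face_normals",
    "boundary_vertex_mask",
]

#: faces with area below this fraction of (bbox diagonal)^2 are rejected at load
DEGENERATE_AREA_REL_TOL = 1e-12


class MeshError(ValueError):
    """Raised for invalid meshes or mesh files."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class TriangulatedSurface:
    """An oriented triangle mesh (the discrete ``S0``, ``S1``, ``S(t)``).

    Parameters
    ----------
    vertices
        ``(N, 3)`` array of vertex positions.
    faces
        ``(F, 3)`` array of vertex indices, counterclockwise winding seen
        from outside.
    name
        Free-form label carried through the pipeline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (N, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"faces must be (F, 3) triangles, got {self.faces.shape}")

    # -- basic properties ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray, name: str | None = None
                      ) -> "TriangulatedSurface":
        """Same topology, new vertex positions (a deformed layer)."""
        return TriangulatedSurface(vertices, self.faces,
                                   self.name if name is None else name)

    def bbox_diagonal(self) -> float:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.linalg.norm(hi - lo))

    def total_area(self) -> float:
        return float(face_areas(self).sum())

    def euler_characteristic(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    # -- validation ---------------------------------------------------------
    def validate(self, check_winding: bool = True) -> "TriangulatedSurface":
        """Check the surface invariants, raising :class:`MeshError` on failure.

        Checks index ranges, the degenerate-face tolerance, and (optionally)
        global winding consistency: every interior edge must appear exactly
        once in each direction.
        """
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshError(
                f"face index out of range: max {self.faces.max()} "
                f"for {self.n_vertices} vertices")
        if not np.isfinite(self.vertices).all():
            raise MeshError("non-finite vertex coordinates")
        diag = self.bbox_diagonal()
        areas = face_areas(self)
        tol = DEGENERATE_AREA_REL_TOL * diag ** 2
        if (areas <= tol).any():
            bad = int(np.argmin(areas))
            raise MeshError(
                f"degenerate face {bad} (area {areas[bad]:.3g} <= {tol:.3g})")
        if check_winding:
            directed = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
            uniq, counts = np.unique(directed, axis=0, return_counts=True)
            if (counts > 1).any():
                raise MeshError("inconsistent winding: repeated directed edge")
        return self

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"TriangulatedSurface(name={self.name!r}, "
                f"{self.n_vertices} vertices, {self.n_faces} faces)")


def _check_field_length(surface: TriangulatedSurface, values: np.ndarray,
                        what: str) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if len(values) != surface.n_vertices:
        raise MeshError(
            f"{what} has length {len(values)}, surface has "
            f"{surface.n_vertices} vertices")
    return values


@dataclass
class VertexScalarField:
    """One scalar per vertex of a referenced surface (thickness, H, tau, ...)."""

    surface: TriangulatedSurface
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = _check_field_length(self.surface, self.values, "scalar field")
        if self.values.ndim != 1:
            raise MeshError("scalar field must be 1-D")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass
class VertexVectorField:
    """One 3-vector per vertex of a referenced surface (normals, velocities)."""

    surface: TriangulatedSurface
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = _check_field_length(self.surface, self.values, "vector field")
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise MeshError("vector field must be (N, 3)")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("off", "ply", "vtk")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshError(f"unsupported mesh format {fmt!r}; use one of {_FORMATS}")
    return fmt


def read_surface(path: str, fmt: str | None = None, name: str | None = None,
                 triangulate: bool = False) -> TriangulatedSurface:
    """Read a surface from an OFF, PLY or VTK legacy polydata file.

    Non-triangular faces are an error unless ``triangulate=True``, in which
    case they are fan-triangulated.
    """
    if not os.path.exists(path):
        raise MeshError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        vertices, faces, _ = _read_vtk(path, triangulate)
    else:
        try:
            mesh = trimesh.load(path, file_type=fmt, process=False, force="mesh")
        except Exception as exc:
            raise MeshError(f"cannot parse {path} as {fmt}: {exc}") from exc
        vertices = np.asarray(mesh.vertices, dtype=np.float64)
        faces = np.asarray(mesh.faces, dtype=np.int64)
        # trimesh triangulates quads silently; detect via the raw file for OFF
        if fmt == "off" and not triangulate and _off_has_polygons(path):
            raise MeshError(f"{path} contains non-triangle faces "
                            "(pass triangulate=True to fan-triangulate)")
    surf = TriangulatedSurface(vertices, faces,
                               name=name or os.path.basename(path))
    return surf.validate()


def _off_has_polygons(path: str) -> bool:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens or tokens[0] != "OFF":
        return False
    nv, nf = int(tokens[1]), int(tokens[2])
    i = 4 + 3 * nv
    for _ in range(nf):
        k = int(tokens[i])
        if k != 3:
            return True
        i += k + 1
    return False


def write_surface(surface: TriangulatedSurface, path: str,
                  fmt: str | None = None,
                  point_data: dict[str, np.ndarray] | None = None,
                  binary: bool = False) -> None:
    """Write a surface to OFF, PLY, or VTK legacy polydata.

    ``point_data`` maps field names to per-vertex scalar ``(N,)`` or vector
    ``(N, 3)`` arrays; only the VTK format carries them (OFF/PLY raise if
    fields are supplied).
    """
    fmt = _infer_format(path, fmt)
    surface.validate(check_winding=False)
    if point_data:
        for fname, values in point_data.items():
            _check_field_length(surface, np.atleast_1d(values), f"field {fname!r}")
        if fmt != "vtk":
            raise MeshError(f"per-vertex fields require the vtk format, not {fmt}")
    if fmt == "vtk":
        _write_vtk(surface, path, point_data or {})
        return
    if fmt == "off":
        # written directly at full double precision (trimesh's OFF/PLY
        # exporters round coordinates to float32)
        lines = ["OFF", f"{surface.n_vertices} {surface.n_faces} 0"]
        lines += [" ".join(f"{c:.17g}" for c in v) for v in surface.vertices]
        lines += ["3 " + " ".join(map(str, tri)) for tri in surface.faces]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:  # ply; coordinates are stored as float32, the format's convention
        mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
        data = trimesh.exchange.ply.export_ply(
            mesh, encoding="binary_little_endian" if binary else "ascii")
        with open(path, "wb") as fh:
            fh.write(data if isinstance(data, bytes) else data.encode())


# -- VTK legacy polydata (ASCII) --------------------------------------------

def _write_vtk(surface: TriangulatedSurface, path: str,
               point_data: dict[str, np.ndarray]) -> None:
    n, f = surface.n_vertices, surface.n_faces
    lines = [
        "# vtk DataFile Version 3.0",
        surface.name or "surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{c:.17g}" for c in v) for v in surface.vertices]
    lines.append(f"POLYGONS {f} {4 * f}")
    lines += ["3 " + " ".join(map(str, tri)) for tri in surface.faces]
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for fname, values in point_data.items():
            values = np.asarray(values, dtype=np.float64)
            if values.ndim == 1:
                lines.append(f"SCALARS {fname} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.17g}" for v in values]
            else:
                lines.append(f"VECTORS {fname} double")
                lines += [" ".join(f"{c:.17g}" for c in v) for v in values]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_vtk(path: str, triangulate: bool):
    with open(path) as fh:
        text = fh.read()
    tokens = text.split()
    pos = 0

    def expect(word):
        nonlocal pos
        while pos < len(tokens) and tokens[pos].upper() != word:
            pos += 1
        if pos >= len(tokens):
            raise MeshError(f"{path}: malformed VTK file (missing {word})")
        pos += 1

    expect("POINTS")
    n = int(tokens[pos]); pos += 2  # skip dtype
    vertices = np.array(tokens[pos:pos + 3 * n], dtype=np.float64).reshape(n, 3)
    pos += 3 * n
    expect("POLYGONS")
    nf = int(tokens[pos]); total = int(tokens[pos + 1]); pos += 2
    raw = np.array(tokens[pos:pos + total], dtype=np.int64)
    pos += total
    faces, i = [], 0
    for _ in range(nf):
        k = int(raw[i])
        poly = raw[i + 1:i + 1 + k]
        i += k + 1
        if k == 3:
            faces.append(poly)
        elif triangulate:
            faces.extend([poly[0], poly[j], poly[j + 1]] for j in range(1, k - 1))
        else:
            raise MeshError(f"{path}: non-triangle face with {k} vertices")
    point_data: dict[str, np.ndarray] = {}
    while pos < len(tokens):
        word = tokens[pos].upper()
        if word == "SCALARS":
            fname = tokens[pos + 1]
            ncomp = int(tokens[pos + 3]) if tokens[pos + 3].isdigit() else 1
            pos += 4
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            point_data[fname] = np.array(
                tokens[pos:pos + n * ncomp], dtype=np.float64)
            pos += n * ncomp
        elif word == "VECTORS":
            fname = tokens[pos + 1]
            pos += 3
            point_data[fname] = np.array(
                tokens[pos:pos + 3 * n], dtype=np.float64).reshape(n, 3)
            pos += 3 * n
        else:
            pos += 1
    return vertices, np.asarray(faces, dtype=np.int64), point_data


def read_vtk_point_data(path: str) -> dict[str, np.ndarray]:
    """Return the named POINT_DATA arrays of a VTK legacy polydata file."""
    return _read_vtk(path, triangulate=False)[2]


# ---------------------------------------------------------------------------
# discrete differential geometry
# ---------------------------------------------------------------------------

def face_corner_vectors(surface: TriangulatedSurface):
    v = surface.vertices[surface.faces]
    return v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]


def face_normals(surface: TriangulatedSurface, unit: bool = True) -> np.ndarray:
    """Face normals; area-weighted (``0.5 * e1 x e2``) when ``unit=False``."""
    e1, e2 = face_corner_vectors(surface)
    nf = 0.5 * np.cross(e1, e2)
    if unit:
        nf = nf / np.linalg.norm(nf, axis=1, keepdims=True)
    return nf


def face_areas(surface: TriangulatedSurface) -> np.ndarray:
    e1, e2 = face_corner_vectors(surface)
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def vertex_normals(surface: TriangulatedSurface) -> np.ndarray:
    """Unit outward vertex normals (area-weighted average of face normals).

    Raises on isolated vertices, which have no incident face to average.
    """
    nf = face_normals(surface, unit=False)  # area weighting
    acc = np.zeros_like(surface.vertices)
    for c in range(3):
        np.add.at(acc, surface.faces[:, c], nf)
    norms = np.linalg.norm(acc, axis=1)
    if (norms == 0).any():
        bad = int(np.argmin(norms))
        raise MeshError(f"vertex {bad} is isolated or has cancelling normals")
    return acc / norms[:, None]


def one_ring_area(surface: TriangulatedSurface) -> np.ndarray:
    """Per-vertex one-ring area: the summed area of all incident triangles."""
    areas = face_areas(surface)
    out = np.zeros(surface.n_vertices)
    for c in range(3):
        np.add.at(out, surface.faces[:, c], areas)
    if (out == 0).any():
        bad = int(np.argmin(out))
        raise MeshError(f"vertex {bad} is isolated (zero one-ring area)")
    return out


def boundary_vertex_mask(surface: TriangulatedSurface) -> np.ndarray:
    """Boolean mask of vertices on the mesh boundary (open surfaces)."""
    directed = surface.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary_edges = uniq[counts == 1]
    mask = np.zeros(surface.n_vertices, dtype=bool)
    mask[boundary_edges.ravel()] = True
    return mask


def _cotangent_laplacian(surface: TriangulatedSurface) -> sp.csr_matrix:
    """Cotangent-weight stiffness matrix L with (L q)_i = sum_j w_ij (q_i - q_j)."""
    f = surface.faces
    v = surface.vertices
    ii, jj, ww = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent at corner a, opposing edge (b, c)
        u = v[f[:, b]] - v[f[:, a]]
        w = v[f[:, c]] - v[f[:, a]]
        cos = np.einsum("ij,ij->i", u, w)
        sin = np.linalg.norm(np.cross(u, w), axis=1)
        cot = cos / np.maximum(sin, 1e-300)
        ii.append(f[:, b]); jj.append(f[:, c]); ww.append(0.5 * cot)
        ii.append(f[:, c]); jj.append(f[:, b]); ww.append(0.5 * cot)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    w = np.concatenate(ww)
    n = surface.n_vertices
    W = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    return sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W


def mean_curvature(surface: TriangulatedSurface) -> np.ndarray:
    """Per-vertex mean curvature, sign convention: sphere with outward
    normals has ``H = -1/r`` (i.e. ``-2H`` is the tangential trace of the
    differential of the outward unit normal).

    Estimator: cotangent Laplacian of the coordinate functions (the
    mean-curvature normal) projected on the vertex normal, with barycentric
    (one-ring / 3) vertex areas.  Values at boundary vertices are computed
    from the partial one-ring and should be masked with
    :func:`boundary_vertex_mask` by the caller.
    """
    L = _cotangent_laplacian(surface)
    area = one_ring_area(surface) / 3.0
    hn = (L @ surface.vertices) / area[:, None]   # approx -Delta q = 2 H~ n
    n = vertex_normals(surface)
    # H~ (positive for a sphere, outward n) -> sign convention H = -H~
    return -0.5 * np.einsum("ij,ij->i", hn, n)


# -- tangential divergence ---------------------------------------------------

def _vertex_adjacency(surface: TriangulatedSurface):
    """Padded (N, R) neighbor index array and validity mask."""
    directed = surface.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.unique(np.sort(directed, axis=1), axis=0)
    both = np.vstack([und, und[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=surface.n_vertices)
    rmax = int(counts.max())
    nbr = np.zeros((surface.n_vertices, rmax), dtype=np.int64)
    mask = np.zeros((surface.n_vertices, rmax), dtype=bool)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    col = np.arange(len(both)) - np.repeat(starts, counts)
    nbr[both[:, 0], col] = both[:, 1]
    mask[both[:, 0], col] = True
    return nbr, mask


def _tangent_basis(normals: np.ndarray):
    """An orthonormal tangent pair (e1, e2) for each unit normal."""
    n = normals
    ref = np.zeros_like(n)
    smallest = np.argmin(np.abs(n), axis=1)
    ref[np.arange(len(n)), smallest] = 1.0
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    return e1, e2


def surface_divergence(surface: TriangulatedSurface, rho: np.ndarray) -> np.ndarray:
    """Discrete tangential divergence ``div_S(rho)`` per vertex.

    ``rho`` is projected on the tangent plane internally.  The differential
    of the field is estimated by a least-squares linear fit over the one-ring
    in a per-vertex tangent orthonormal basis, and the divergence is its
    tangential trace ``e1^T D(rho) e1 + e2^T D(rho) e2``.
    """
    rho = _check_field_length(surface, rho, "vector field")
    n = vertex_normals(surface)
    rho_t = rho - np.einsum("ij,ij->i", rho, n)[:, None] * n
    e1, e2 = _tangent_basis(n)
    nbr, mask = _vertex_adjacency(surface)
    dx = surface.vertices[nbr] - surface.vertices[:, None, :]   # (N, R, 3)
    drho = rho_t[nbr] - rho_t[:, None, :]
    u1 = np.einsum("nrj,nj->nr", dx, e1)
    u2 = np.einsum("nrj,nj->nr", dx, e2)
    w = mask.astype(np.float64)
    # normal equations for D (3x2) per vertex: D = Y^T U (U^T U)^-1
    a11 = np.sum(w * u1 * u1, axis=1)
    a12 = np.sum(w * u1 * u2, axis=1)
    a22 = np.sum(w * u2 * u2, axis=1)
    b1 = np.einsum("nr,nrj->nj", w * u1, drho)   # (N, 3)
    b2 = np.einsum("nr,nrj->nj", w * u2, drho)
    det = a11 * a22 - a12 ** 2
    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
    d1 = (a22[:, None] * b1 - a12[:, None] * b2) / det[:, None]  # D[:, 0]
    d2 = (-a12[:, None] * b1 + a11[:, None] * b2) / det[:, None]
    return np.einsum("nj,nj->n", e1, d1) + np.einsum("nj,nj->n", e2, d2)
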