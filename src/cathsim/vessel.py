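"""Vessel-wall geometry: triangulated lumen surfaces, tube phantoms, plane primitives.

The vessel wall is a triangle mesh whose per-triangle planes are stored with
*inward*-oriented unit normals ``n`` and offsets ``d`` such that the plane is
``{x : n·x + d = 0}``.  With this convention the signed distance
``g(x) = n·x + d`` is positive on the lumen side and negative beyond the wall,
so a catheter node's penetration depth is ``max(0, -g(x))``.

Units are millimetres throughout.  Coordinates are right-handed Cartesian 3D;
vertex indices are 0-based in memory (OBJ files are 1-based on disk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptyMeshError, MeshFormatError, ValidationError

_DEGENERATE_AREA = 1e-12  # mm^2; triangles below this have no defined plane


@dataclass
class VesselMesh:
    """Triangulated vessel wall with inward-oriented per-triangle planes.

    Attributes
    ----------
    vertices : (M, 3) float array, mm
    triangles : (T, 3) int array of vertex indices
    normals : (T, 3) float array, unit, oriented toward the lumen interior
    offsets : (T,) float array, plane offsets d with n·v + d = 0 on the triangle
    """

    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray = field(default=None)  # type: ignore[assignment]
    offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if len(self.triangles) == 0:
            raise EmptyMeshError("mesh has no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise ValidationError("triangle index out of range")
        if self.normals is None or self.offsets is None:
            n, d = _face_planes(self.vertices, self.triangles)
            self.normals, self.offsets = n, d
        else:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            self.offsets = np.asarray(self.offsets, dtype=float).reshape(-1)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_vertices(self, tri: int) -> np.ndarray:
        """(3, 3) array of the triangle's corner coordinates."""
        return self.vertices[self.triangles[tri]]

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def flip(self, mask=None) -> None:
        """Reverse normal orientation of the selected triangles (default: all)."""
        if mask is None:
            mask = np.ones(self.n_triangles, dtype=bool)
        self.normals[mask] *= -1.0
        self.offsets[mask] *= -1.0

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "VesselMesh":
        """Return a copy rigidly transformed by x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        v = self.vertices @ R.T + t
        n = self.normals @ R.T
        d = self.offsets - n @ t
        return VesselMesh(v, self.triangles.copy(), n, d)


@dataclass(frozen=True)
class TubeSpec:
    """Parameters of a synthetic tube phantom standing in for a plastic-tube vessel.

    A ``straight`` tube runs along +x from the origin.  A ``curved`` tube is an
    entry straight along +x, a circular bend of ``bend_radius`` through
    ``bend_angle`` radians in the xy-plane (turning toward +y), then an exit
    straight; ``length`` is ignored for curved tubes.
    """

    radius: float
    kind: str = "straight"  # "straight" | "curved"
    length: float = 100.0
    bend_radius: float = 20.0
    bend_angle: float = 0.0  # radians
    entry_length: float = 20.0
    exit_length: float = 20.0
    circumferential_resolution: int = 16
    axial_resolution: int = 20
    capped_end: bool = False

    def validate(self) -> None:
        if self.radius <= 0:
            raise ValidationError("tube radius must be > 0")
        if self.kind not in ("straight", "curved"):
            raise ValidationError(f"unknown tube kind {self.kind!r}")
        if self.circumferential_resolution < 6:
            raise ValidationError("circumferential resolution must be >= 6")
        if self.axial_resolution < 2:
            raise ValidationError("axial resolution must be >= 2")
        if self.kind == "straight" and self.length <= 0:
            raise ValidationError("straight tube length must be > 0")
        if self.kind == "curved":
            if self.bend_radius <= 0:
                raise ValidationError("bend radius must be > 0")
            if self.bend_angle < 0:
                raise ValidationError("bend angle must be >= 0")
            if self.entry_length < 0 or self.exit_length < 0:
                raise ValidationError("entry/exit lengths must be >= 0")

    def total_length(self) -> float:
        """Centerline arc length of the phantom."""
        if self.kind == "straight":
            return self.length
        return self.entry_length + self.bend_radius * self.bend_angle + self.exit_length

    def centerline(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Centerline point and unit tangent at arc length(s) ``s``.

        Returns (points, tangents), each (len(s), 3) for array input.
        """
        s = np.atleast_1d(np.asarray(s, dtype=float))
        p = np.zeros((len(s), 3))
        t = np.zeros((len(s), 3))
        if self.kind == "straight":
            p[:, 0] = s
            t[:, 0] = 1.0
            return p, t
        L1 = self.entry_length
        La = self.bend_radius * self.bend_angle
        R = self.bend_radius
        a_end = self.bend_angle
        center = np.array([L1, R, 0.0])
        t_end = np.array([np.cos(a_end), np.sin(a_end), 0.0])
        p_end = center + R * np.array([np.sin(a_end), -np.cos(a_end), 0.0])
        for k, sk in enumerate(s):
            if sk <= L1:
                p[k] = [sk, 0.0, 0.0]
                t[k] = [1.0, 0.0, 0.0]
            elif sk <= L1 + La:
                a = (sk - L1) / R
                p[k] = center + R * np.array([np.sin(a), -np.cos(a), 0.0])
                t[k] = [np.cos(a), np.sin(a), 0.0]
            else:
                p[k] = p_end + (sk - L1 - La) * t_end
                t[k] = t_end
        return p, t


def _face_planes(vertices: np.ndarray, triangles: np.ndarray):
    """Unit normals and offsets from winding; raises on degenerate faces."""
    tv = vertices[triangles]
    cross = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    if np.any(norm < 2 * _DEGENERATE_AREA):
        raise ValidationError("degenerate (zero-area) triangle")
    n = cross / norm[:, None]
    d = -np.einsum("ij,ij->i", n, tv[:, 0])
    return n, d


def triangle_plane(mesh: VesselMesh, tri: int):
    """Stored inward-oriented plane of triangle ``tri`` as ``(normal, offset)``."""
    if not 0 <= tri < mesh.n_triangles:
        raise IndexError(f"triangle index {tri} out of range")
    return mesh.normals[tri].copy(), float(mesh.offsets[tri])


def signed_distance(mesh: VesselMesh, tri: int, p) -> float:
    """Signed plane distance g(p) = n·p + d; positive on the lumen side."""
    n, d = triangle_plane(mesh, tri)
    return float(n @ np.asarray(p, dtype=float) + d)


# ---------------------------------------------------------------------------
# Tube phantom generation


def make_tube(spec: TubeSpec) -> VesselMesh:
    """Generate a triangulated tube phantom with inward-oriented normals.

    The surface is a regular grid of ``axial_resolution + 1`` rings of
    ``circumferential_resolution`` vertices each; every vertex lies at exactly
    ``spec.radius`` from the analytic centerline.  With ``capped_end`` a
    triangle fan closes the far end (for dead-end push scenarios).
    """
    spec.validate()
    nc = spec.circumferential_resolution
    na = spec.axial_resolution
    L = spec.total_length()
    s = np.linspace(0.0, L, na + 1)
    centers, tangents = spec.centerline(s)
    # frame: e1 in-plane normal (xy), e2 = z; continuous along the centerline
    e1 = np.stack([-tangents[:, 1], tangents[:, 0], np.zeros(len(s))], axis=1)
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    # half-facet phase offset keeps facet centers (not vertex seams) on the
    # z = 0 bend plane, where plane-projection contact tests are most exercised
    phi = 2 * np.pi * (np.arange(nc) + 0.5) / nc
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    # ring j vertex i at index j*nc + i
    verts = (
        centers[:, None, :]
        + spec.radius * (cos_p[None, :, None] * e1[:, None, :] + sin_p[None, :, None] * e2[:, None, :])
    ).reshape(-1, 3)
    faces = []
    for j in range(na):
        base0, base1 = j * nc, (j + 1) * nc
        for i in range(nc):
            i2 = (i + 1) % nc
            faces.append([base0 + i, base0 + i2, base1 + i])
            faces.append([base0 + i2, base1 + i2, base1 + i])
    verts_list = [verts]
    if spec.capped_end:
        cap_center_idx = len(verts)
        verts_list.append(centers[-1][None, :])
        base = na * nc
        for i in range(nc):
            faces.append([base + i, base + (i + 1) % nc, cap_center_idx])
    vertices = np.vstack(verts_list)
    triangles = np.asarray(faces, dtype=int)
    mesh = VesselMesh(vertices, triangles)
    _orient_inward_analytic(mesh, spec, s)
    if spec.capped_end:
        # cap planes are perpendicular to the radial direction, so the
        # centerline vote is ill-defined for them; inward means against the
        # end tangent (back into the tube)
        cap = np.arange(mesh.n_triangles - nc, mesh.n_triangles)
        outward = mesh.normals[cap] @ tangents[-1] > 0
        flip_mask = np.zeros(mesh.n_triangles, dtype=bool)
        flip_mask[cap[outward]] = True
        mesh.flip(flip_mask)
    return mesh


def _orient_inward_analytic(mesh: VesselMesh, spec: TubeSpec, ring_s: np.ndarray) -> None:
    """Flip faces whose normal points away from the nearest centerline sample."""
    cent = mesh.centroids()
    # nearest centerline sample per centroid (dense sampling along arc length)
    s_fine = np.linspace(0.0, spec.total_length(), 8 * len(ring_s))
    pts, _ = spec.centerline(s_fine)
    d2 = ((cent[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    nearest = pts[np.argmin(d2, axis=1)]
    outward = np.einsum("ij,ij->i", mesh.normals, cent - nearest) > 0
    mesh.flip(outward)


# ---------------------------------------------------------------------------
# Mesh I/O


def _detect_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in ("obj", "stl"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (expected obj or stl)")
    return fmt


def load_mesh(path, fmt: str | None = None) -> VesselMesh:
    """Load an OBJ or STL surface and orient its normals toward the lumen.

    Degenerate (area < 1e-12 mm^2) triangles are dropped with a warning.
    STL triangle soups are welded on exact duplicate coordinates.
    """
    fmt = _detect_format(path, fmt)
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - trimesh raises various types
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path}: no triangles")
        tm = geoms[0]
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=int)
    if faces.size == 0:
        raise EmptyMeshError(f"{path}: no triangles")
    if fmt == "stl":
        vertices, faces = _weld_exact(vertices, faces)
    # drop degenerate faces
    tv = vertices[faces]
    area2 = np.linalg.norm(np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0]), axis=1)
    bad = area2 < 2 * _DEGENERATE_AREA
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} degenerate triangle(s)", stacklevel=2)
        faces = faces[~bad]
        if len(faces) == 0:
            raise EmptyMeshError(f"{path}: all triangles degenerate")
    mesh = VesselMesh(vertices, faces)
    orient_inward(mesh)
    return mesh


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge bitwise-identical vertices (STL stores a triangle soup)."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[faces]


def orient_inward(mesh: VesselMesh, n_samples: int = 64) -> None:
    """Globally orient normals toward the enclosed lumen by ray-parity majority vote.

    From each sampled triangle centroid a ray is cast along the face normal;
    an odd number of crossings with the rest of the surface means that normal
    already points into the enclosed region.  Assumes consistent winding.
    """
    rng = np.random.default_rng(0)  # fixed: orientation must be deterministic
    k = min(n_samples, mesh.n_triangles)
    idx = rng.choice(mesh.n_triangles, size=k, replace=False)
    cent = mesh.centroids()[idx]
    dirs = mesh.normals[idx]
    origins = cent + 1e-6 * dirs
    crossings = _count_ray_crossings(mesh, origins, dirs)
    inward_votes = int(np.sum(crossings % 2 == 1))
    if inward_votes < k - inward_votes:
        mesh.flip()


def _count_ray_crossings(mesh: VesselMesh, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Number of triangle crossings of each ray (vectorized plane + barycentric test)."""
    n, d = mesh.normals, mesh.offsets
    denom = dirs @ n.T  # (R, T)
    numer = -(origins @ n.T + d[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_hit = np.where(np.abs(denom) > 1e-12, numer / denom, -1.0)
    counts = np.zeros(len(origins), dtype=int)
    tv = mesh.vertices[mesh.triangles]
    for r in range(len(origins)):
        cand = np.nonzero(t_hit[r] > 1e-9)[0]
        if len(cand) == 0:
            continue
        pts = origins[r] + t_hit[r, cand, None] * dirs[r]
        inside = _points_in_triangles(pts, tv[cand])
        counts[r] = int(inside.sum())
    return counts


def _points_in_triangles(points: np.ndarray, tri_verts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Barycentric inside test for point k against triangle k (paired arrays)."""
    v0 = tri_verts[:, 0]
    e0 = tri_verts[:, 1] - v0
    e1 = tri_verts[:, 2] - v0
    w = points - v0
    a = np.einsum("ij,ij->i", e0, e0)
    b = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    p = np.einsum("ij,ij->i", w, e0)
    q = np.einsum("ij,ij->i", w, e1)
    det = a * c - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (c * p - b * q) / det
        v = (a * q - b * p) / det
    ok = det > 0
    return ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol)


def save_mesh(mesh: VesselMesh, path, fmt: str | None = None) -> None:
    """Write an OBJ or ASCII STL file with shortest-round-trip coordinates."""
    fmt = _detect_format(path, fmt)
    path = Path(path)
    if fmt == "obj":
        lines = ["# cathsim vessel mesh"]
        for v in mesh.vertices:
            lines.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
        for f in mesh.triangles:
            lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
        path.write_text("\n".join(lines) + "\n")
    else:
        lines = ["solid cathsim"]
        tv = mesh.vertices[mesh.triangles]
        for n, tri in zip(mesh.normals, tv):
            lines.append(f"facet normal {n[0]:.17g} {n[1]:.17g} {n[2]:.17g}")
            lines.append("  outer loop")
            for v in tri:
                lines.append(f"    vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
            lines.append("  endloop")
            lines.append("endfacet")
        lines.append("endsolid cathsim")
        path.write_text("\n".join(lines) + "\n")
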