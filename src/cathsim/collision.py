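"""Node-versus-wall collision detection producing the active contact set.

Contacts are node-triangle pairs: a catheter node contacts a vessel triangle
when its signed plane distance g(x) = n·x + d falls at or below ``margin``
*and* its orthogonal projection onto the triangle's plane lies inside the
triangle (barycentric test with a small edge tolerance).  A node touching
several triangles (mesh creases, caps) yields one contact per triangle — each
contributes its own penalty term.

Detection is a vectorized all-pairs plane-distance test with an AABB
prefilter; it is exactly equivalent to brute-force enumeration.  The base
node x_0 is boundary-fixed and never contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vessel import VesselMesh

BARYCENTRIC_TOL = 1e-9


@dataclass(frozen=True)
class Contact:
    """Active contact between catheter node ``node`` and mesh triangle ``triangle``."""

    node: int
    triangle: int
    normal: np.ndarray  # inward unit normal of the triangle's plane
    offset: float
    penetration: float  # mm, max(0, -(n·x + d)) at detection time


class ContactSet:
    """Ordered, duplicate-free collection of contacts ((node, triangle) lexicographic)."""

    def __init__(self, contacts=()):
        seen = {}
        for ct in contacts:
            seen[(ct.node, ct.triangle)] = ct
        self.contacts = [seen[k] for k in sorted(seen)]

    def __iter__(self):
        return iter(self.contacts)

    def __len__(self):
        return len(self.contacts)

    def __bool__(self):
        return bool(self.contacts)

    def pairs(self) -> tuple:
        return tuple((ct.node, ct.triangle) for ct in self.contacts)

    def penetrations(self) -> np.ndarray:
        return np.array([ct.penetration for ct in self.contacts])

    def max_penetration(self) -> float:
        return float(self.penetrations().max()) if self.contacts else 0.0


def _candidate_mask(mesh: VesselMesh, positions: np.ndarray, margin: float,
                    signed: np.ndarray) -> np.ndarray:
    """AABB prefilter: nodes near each triangle's box, intersected with the plane test."""
    tv = mesh.vertices[mesh.triangles]  # (T, 3, 3)
    lo = tv.min(axis=1) - (margin + BARYCENTRIC_TOL)  # box grown by margin
    hi = tv.max(axis=1) + (margin + BARYCENTRIC_TOL)
    # a node can only project inside a triangle if it is within the slab of the
    # triangle's AABB grown by its distance to the plane
    dist = np.abs(signed)  # (P, T)
    in_box = np.all(
        (positions[:, None, :] >= lo[None, :, :] - dist[:, :, None])
        & (positions[:, None, :] <= hi[None, :, :] + dist[:, :, None]),
        axis=2,
    )
    return in_box


def detect_contacts(mesh: VesselMesh, positions, margin: float = 0.0) -> ContactSet:
    """Find all node-triangle contacts for catheter nodes 1 … N-1.

    ``positions`` is the full (N, 3) node array; node 0 is skipped (pinned).
    With the default margin 0 only true penetration (and exact touching)
    registers.  Deterministic: output order is (node, triangle) lexicographic.
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    if len(positions) <= 1:
        return ContactSet()
    pos = positions[1:]
    signed = pos @ mesh.normals.T + mesh.offsets[None, :]  # (P, T)
    near = signed <= margin + 1e-12
    near &= _candidate_mask(mesh, pos, margin, signed)
    rows, cols = np.nonzero(near)
    if len(rows) == 0:
        return ContactSet()
    # project candidate nodes onto their triangle planes and run the inside test
    n = mesh.normals[cols]
    s = signed[rows, cols]
    proj = pos[rows] - s[:, None] * n
    tv = mesh.vertices[mesh.triangles[cols]]
    inside = _barycentric_inside(proj, tv)
    contacts = []
    for k in np.nonzero(inside)[0]:
        tri = int(cols[k])
        contacts.append(Contact(
            node=int(rows[k]) + 1,
            triangle=tri,
            normal=mesh.normals[tri].copy(),
            offset=float(mesh.offsets[tri]),
            penetration=float(max(0.0, -s[k])),
        ))
    return ContactSet(contacts)


def _barycentric_inside(points: np.ndarray, tri_verts: np.ndarray,
                        tol: float = BARYCENTRIC_TOL) -> np.ndarray:
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
    return (det > 0) & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol)


def detect_contacts_bruteforce(mesh: VesselMesh, positions, margin: float = 0.0) -> ContactSet:
    """Reference all-pairs detector (no prefilter); used to validate detect_contacts."""
    positions = np.asarray(positions, float).reshape(-1, 3)
    contacts = []
    for i in range(1, len(positions)):
        x = positions[i]
        for tri in range(mesh.n_triangles):
            n, d = mesh.normals[tri], mesh.offsets[tri]
            s = float(n @ x + d)
            if s > margin + 1e-12:
                continue
            proj = (x - s * n)[None, :]
            if _barycentric_inside(proj, mesh.vertices[mesh.triangles[tri]][None, :, :])[0]:
                contacts.append(Contact(i, tri, n.copy(), float(d), max(0.0, -s)))
    return ContactSet(contacts)


def max_penetration(mesh: VesselMesh, positions) -> float:
    """Deepest wall penetration over all nodes (0 if every node is inside).

    A node counts as penetrating a triangle only when its plane projection
    falls inside that triangle, mirroring the contact model's resolution.
    Unlike :func:`detect_contacts` the pinned base node is included — this is
    a diagnostic, not an energy term.
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    if len(positions) == 0:
        return 0.0
    signed = positions @ mesh.normals.T + mesh.offsets[None, :]
    pen = signed < -1e-15
    rows, cols = np.nonzero(pen)
    if len(rows) == 0:
        return 0.0
    s = signed[rows, cols]
    proj = positions[rows] - s[:, None] * mesh.normals[cols]
    inside = _barycentric_inside(proj, mesh.vertices[mesh.triangles[cols]])
    if not inside.any():
        return 0.0
    return float(-s[inside].min())
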