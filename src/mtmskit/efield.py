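"""Quasi-static E-field forward model for spherically symmetric conductors.

The induced electric field at a point ``r`` inside a spherically symmetric
volume conductor is obtained from the reciprocity between magnetic lead
fields and inductive stimulation: the component of ``E`` along a unit vector
``p`` equals ``-dI/dt`` times the magnetic flux that a unit current dipole
``p`` placed at ``r`` would send through the stimulating circuit.  For a
sphere the external field of an internal current dipole has the closed-form
Sarvas solution, so the total field (primary ``-dA/dt`` plus the secondary
surface-charge term) is evaluated in closed form without any volume or
surface discretization of the conductor.  Two consequences of the spherical
symmetry fall out of the formula automatically: the induced field is purely
tangential, and it is independent of the radial conductivity profile.

A coil is represented either as discrete wire loops (flux integrated over a
fan-triangulated spanning surface of each loop) or as a stream function
``psi`` on a planar mesh (flux weighted by ``psi``, using the equivalence of
a stream-function surface current to a sheet of magnetic dipoles of surface
density ``psi * n``).

Inductances use the Neumann double integral: over elementary stream-function
loops for the design energy matrix, and over the physical wire segments
(with a wire-radius self-term) for manufactured windings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import SphericalHeadModel, TriMesh, WindingPath

MU0 = 4e-7 * np.pi
COPPER_RESISTIVITY = 1.68e-8  # ohm m, annealed copper at DC

__all__ = [
    "EFieldMap",
    "BasisMatrix",
    "InductanceMatrix",
    "efield_segments",
    "efield_basis",
    "inductance_matrix",
    "winding_inductance",
    "winding_resistance",
    "InvalidGeometryError",
]


class InvalidGeometryError(ValueError):
    """Coil and conductor geometry are inconsistent (e.g. intersecting)."""


@dataclass
class EFieldMap:
    """E-field per unit coil-current slew rate at a set of points.

    ``vectors[i]`` is the field at ``points[i]`` in V/m per (A/s).
    """

    points: np.ndarray  # (n, 3) m
    vectors: np.ndarray  # (n, 3) V/m per A/s
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.points.shape != self.vectors.shape or self.points.ndim != 2:
            raise ValueError("points and vectors must both be (n, 3)")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def scaled(self, factor: float) -> "EFieldMap":
        return EFieldMap(self.points, self.vectors * factor, self.source_id)

    def __add__(self, other: "EFieldMap") -> "EFieldMap":
        if not np.allclose(self.points, other.points):
            raise ValueError("maps are defined on different point sets")
        return EFieldMap(self.points, self.vectors + other.vectors,
                         f"{self.source_id}+{other.source_id}")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            np.hstack([self.points, self.vectors]),
            columns=["x", "y", "z", "Ex", "Ey", "Ez"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source_id: str = "") -> "EFieldMap":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df[["x", "y", "z"]].to_numpy(),
            df[["Ex", "Ey", "Ez"]].to_numpy(),
            source_id=source_id,
        )


@dataclass
class BasisMatrix:
    """Linear map from stream-function vertex values to E-field samples.

    ``matrix`` has shape (3*n_points, n_interior): column ``j`` is the field
    of a unit elementary current loop (hat function) at interior vertex
    ``interior_idx[j]``; boundary vertices are excluded (psi = 0 there).
    """

    matrix: np.ndarray
    points: np.ndarray
    interior_idx: np.ndarray
    mesh: TriMesh

    def field_of(self, psi_interior: np.ndarray, source_id: str = "stream") -> EFieldMap:
        vec = (self.matrix @ psi_interior).reshape(-1, 3)
        return EFieldMap(self.points, vec, source_id=source_id)


@dataclass
class InductanceMatrix:
    """Mutual inductances of elementary stream-function loops (henry).

    Symmetric positive definite; the quadratic form ``0.5 * psi L psi`` is
    the magnetic energy of the surface current at 1 A stream-function scale.
    """

    matrix: np.ndarray
    interior_idx: np.ndarray

    def energy(self, psi_interior: np.ndarray) -> float:
        return float(0.5 * psi_interior @ self.matrix @ psi_interior)


# ---------------------------------------------------------------------------
# Reciprocity core
# ---------------------------------------------------------------------------


def _reciprocity_efield(
    eval_pts: np.ndarray,
    quad_pts: np.ndarray,
    quad_wpsi: np.ndarray,
    quad_normals: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Total E per unit dI/dt at ``eval_pts`` (sphere-centred coordinates).

    ``quad_pts`` sample the coil's spanning surface(s); ``quad_wpsi`` is the
    quadrature weight times the local stream-function value (signed area for
    discrete loops); ``quad_normals`` the surface orientation.

    For a unit dipole ``p`` at r, the flux of its Sarvas field through the
    surface element (q, n, w) is ``mu0/(4 pi F^2) * (p x r) . u * w`` with
    ``u = F n - (n . grad F) q``; summing and applying reciprocity
    ``E = -dI/dt * flux`` yields ``E(r) = -mu0/(4 pi) r x sum(w psi u / F^2)``.
    """
    eval_pts = np.asarray(eval_pts, dtype=float)
    q = np.asarray(quad_pts, dtype=float)
    w = np.asarray(quad_wpsi, dtype=float)
    n = np.asarray(quad_normals, dtype=float)
    rm = np.linalg.norm(q, axis=1)  # |r'| of observation/quadrature points

    E = np.empty_like(eval_pts)
    for lo in range(0, len(eval_pts), chunk):
        r = eval_pts[lo : lo + chunk]  # (b, 3) dipole positions
        a = q[None, :, :] - r[:, None, :]  # (b, m, 3)
        amag = np.linalg.norm(a, axis=2)  # (b, m)
        adotq = np.einsum("bmj,mj->bm", a, q)
        rdotq = r @ q.T  # (b, m)
        F = amag * (rm * amag + rm**2 - rdotq)
        c1 = amag**2 / rm + adotq / amag + 2.0 * amag + 2.0 * rm
        c2 = amag + 2.0 * rm + adotq / amag
        # grad F = c1 * q - c2 * r ; u = F n - (n . grad F) q
        ndotq = np.einsum("mj,mj->m", n, q)
        ndotgF = c1 * ndotq[None, :] - c2 * (r @ n.T)
        # S = sum_m w_m (F n - (n.gradF) q) / F^2
        invF2 = 1.0 / F**2
        Sn = (w * F * invF2) @ n
        Sq = np.einsum("bm,mj->bj", w * invF2 * ndotgF, q)
        S = Sn - Sq
        E[lo : lo + chunk] = -(MU0 / (4.0 * np.pi)) * np.cross(r, S)
    return E


def _fan_quadrature(loop: np.ndarray, refine: int = 2):
    """Signed-triangle fan quadrature over the surface spanned by a loop.

    The fan from the loop centroid spans any closed (planar or mildly
    non-planar) polygon with correctly signed areas; each fan triangle is
    uniformly subdivided ``refine`` times and sampled at sub-triangle
    centroids.  Returns (points, signed_area_weights, unit_normals).
    """
    pts = np.asarray(loop, dtype=float)
    c = pts[:-1].mean(axis=0)
    p0 = pts[:-1]
    p1 = pts[1:]
    tris = np.stack([np.broadcast_to(c, p0.shape), p0, p1], axis=1)  # (k,3,3)
    for _ in range(refine):
        a, b, d = tris[:, 0], tris[:, 1], tris[:, 2]
        ab, bd, da = (a + b) / 2, (b + d) / 2, (d + a) / 2
        tris = np.concatenate(
            [
                np.stack([a, ab, da], axis=1),
                np.stack([ab, b, bd], axis=1),
                np.stack([da, bd, d], axis=1),
                np.stack([ab, bd, da], axis=1),
            ],
            axis=0,
        )
    cross = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    keep = area2 > 0
    tris, cross, area2 = tris[keep], cross[keep], area2[keep]
    normals = cross / area2[:, None]
    weights = 0.5 * area2
    centroids = tris.mean(axis=1)
    return centroids, weights, normals


def _check_points_inside(points: np.ndarray, head: SphericalHeadModel) -> None:
    r = np.linalg.norm(points - head.center, axis=1)
    if np.any(r > head.radius * (1 + 1e-9)):
        raise InvalidGeometryError("evaluation points must lie inside the conductor")


def efield_segments(
    winding: WindingPath,
    head: SphericalHeadModel,
    points: np.ndarray,
    refine: int = 2,
) -> EFieldMap:
    """E-field per unit dI/dt of a series-connected discrete winding.

    All turns carry the same current I(t); each loop contributes with its
    polarity sign.  ``refine`` controls the loop-surface quadrature depth.
    """
    points = np.asarray(points, dtype=float)
    _check_points_inside(points, head)
    for loop in winding.loops:
        d = np.linalg.norm(loop - head.center, axis=1)
        if np.any(d < head.radius * (1 - 1e-9)):
            raise InvalidGeometryError("winding intersects the conductor sphere")

    qs, ws, ns = [], [], []
    for loop, pol in zip(winding.loops, winding.polarities):
        pts, w, n = _fan_quadrature(loop, refine=refine)
        qs.append(pts)
        ws.append(pol * w)
        ns.append(n)
    quad_pts = np.vstack(qs) - head.center
    quad_w = np.concatenate(ws)
    quad_n = np.vstack(ns)
    E = _reciprocity_efield(points - head.center, quad_pts, quad_w, quad_n)
    return EFieldMap(points, E, source_id="winding")


def _plane_quadrature(mesh: TriMesh):
    """Degree-2 (3-point) quadrature points, weights and hat values per face."""
    v = mesh.vertices
    f = mesh.faces
    areas = mesh.triangle_areas()
    normals = mesh.triangle_normals()
    # barycentric (2/3, 1/6, 1/6) cyclic
    bary = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3]])
    pts = np.einsum("qb,fbj->fqj", bary, v[f])  # (nf, 3, 3)
    w = np.repeat(areas / 3.0, 3)
    n = np.repeat(normals, 3, axis=0)
    return pts.reshape(-1, 3), w, n, bary


def efield_basis(
    coil_mesh: TriMesh,
    head: SphericalHeadModel,
    points: np.ndarray,
    chunk: int = 128,
) -> BasisMatrix:
    """Field basis of elementary stream-function loops on a planar coil mesh.

    Column ``j`` of the returned matrix is the E-field (stacked x,y,z per
    point, V/m per A/s) of a unit-amplitude hat function at interior vertex
    ``j``; boundary vertices are excluded since the stream function vanishes
    on the coil boundary.
    """
    points = np.asarray(points, dtype=float)
    _check_points_inside(points, head)
    d = np.linalg.norm(coil_mesh.vertices - head.center, axis=1)
    if np.any(d < head.radius * (1 + 1e-12)):
        raise InvalidGeometryError("coil plane touches or enters the conductor sphere")

    if coil_mesh.boundary_mask is not None:
        boundary = np.flatnonzero(coil_mesh.boundary_mask)
    else:
        boundary = coil_mesh.boundary_vertices()
    interior = np.setdiff1d(np.arange(coil_mesh.n_vertices), boundary)

    quad_pts, w, n, bary = _plane_quadrature(coil_mesh)
    quad_pts = quad_pts - head.center
    eval_pts = points - head.center
    rm = np.linalg.norm(quad_pts, axis=1)
    ndotq = np.einsum("mj,mj->m", n, quad_pts)

    # sparse hat-value matrix H (n_quad, n_vertices): psi at quad points = H psi
    from scipy.sparse import coo_matrix

    nf = coil_mesh.n_faces
    rows = []
    cols = []
    vals = []
    for q in range(3):
        for b in range(3):
            rows.append(np.arange(nf) * 3 + q)
            cols.append(coil_mesh.faces[:, b])
            vals.append(np.full(nf, bary[q, b]))
    H = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * nf, coil_mesh.n_vertices),
    ).tocsc()[:, interior]

    M = np.empty((len(points), 3, len(interior)))
    const = -(MU0 / (4.0 * np.pi))
    for lo in range(0, len(eval_pts), chunk):
        r = eval_pts[lo : lo + chunk]
        a = quad_pts[None, :, :] - r[:, None, :]
        amag = np.linalg.norm(a, axis=2)
        adotq = np.einsum("bmj,mj->bm", a, quad_pts)
        rdotq = r @ quad_pts.T
        F = amag * (rm * amag + rm**2 - rdotq)
        c1 = amag**2 / rm + adotq / amag + 2.0 * amag + 2.0 * rm
        c2 = amag + 2.0 * rm + adotq / amag
        ndotgF = c1 * ndotq[None, :] - c2 * (r @ n.T)
        invF2 = 1.0 / F**2
        # per-quad-point vector integrand u/F^2 weighted by w
        coefn = w * invF2 * F  # (b, m)
        coefq = w * invF2 * ndotgF
        # E_j(r) = const * r x (sum_m H_mj (coefn_m n_m - coefq_m q_m))
        Gn = np.stack([(coefn * n[:, k]) @ H for k in range(3)], axis=1)  # b,3,ni
        Gq = np.stack([(coefq * quad_pts[:, k]) @ H for k in range(3)], axis=1)
        G = Gn - Gq  # (b, 3, ni)
        M[lo : lo + chunk] = const * np.cross(
            r[:, :, None], G, axisa=1, axisb=1, axisc=1
        )
    matrix = M.reshape(len(points) * 3, len(interior))
    return BasisMatrix(matrix=matrix, points=points, interior_idx=interior, mesh=coil_mesh)


# ---------------------------------------------------------------------------
# Inductance
# ---------------------------------------------------------------------------


def _hat_current_basis(mesh: TriMesh):
    """Per-triangle surface-current direction of each vertex hat function.

    Surface current of a stream function: K = grad(psi) x n.  Returns D with
    shape (n_faces, 3, 3): D[f, corner, :] is the (constant) current vector on
    face f contributed by a unit hat at its ``corner``-th vertex.
    """
    v = mesh.vertices
    f = mesh.faces
    areas = mesh.triangle_areas()
    normals = mesh.triangle_normals()
    D = np.empty((mesh.n_faces, 3, 3))
    for corner in range(3):
        e = v[f[:, (corner + 2) % 3]] - v[f[:, (corner + 1) % 3]]
        grad = np.cross(normals, e) / (2.0 * areas[:, None])
        D[:, corner, :] = np.cross(grad, normals)
    return D


def _triangle_self_inv_distance(mesh: TriMesh) -> np.ndarray:
    """Approximate mean inverse distance <1/R> over each triangle with itself.

    Uses the self-similar subdivision identity: splitting T into 4 similar
    children, I(T) = S_offdiag + 4 I(T/2) with I proportional to A^{3/2},
    giving I(T) = 2 * S_offdiag, applied after one refinement level.
    Returned value is I / A^2 (i.e. <1/R>).
    """
    v = mesh.vertices[mesh.faces]  # (nf, 3, 3)
    a, b, c = v[:, 0], v[:, 1], v[:, 2]
    ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
    children = np.stack(
        [
            np.stack([a, ab, ca], axis=1),
            np.stack([ab, b, bc], axis=1),
            np.stack([ca, bc, c], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ],
        axis=1,
    )  # (nf, 4, 3, 3)
    cent = children.mean(axis=2)  # (nf, 4, 3)
    areas4 = mesh.triangle_areas()[:, None] / 4.0
    S = np.zeros(mesh.n_faces)
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            d = np.linalg.norm(cent[:, i] - cent[:, j], axis=1)
            S += (areas4[:, 0] ** 2) / d
    I = 2.0 * S  # double integral of 1/R over T x T
    return I / mesh.triangle_areas() ** 2


def inductance_matrix(coil_mesh: TriMesh, near_factor: float = 2.0) -> InductanceMatrix:
    """Neumann inductance matrix of the elementary stream-function loops.

    ``L[i, j] = mu0/(4 pi) * integral (K_i . K_j)/|r - r'| dS dS'`` over the
    coil surface, with centroid quadrature for well-separated triangle pairs,
    4-fold subdivision for near pairs, and a self-similar estimate for the
    singular self terms.  The result is symmetric positive definite.
    """
    if coil_mesh.boundary_mask is not None:
        boundary = np.flatnonzero(coil_mesh.boundary_mask)
    else:
        boundary = coil_mesh.boundary_vertices()
    interior = np.setdiff1d(np.arange(coil_mesh.n_vertices), boundary)

    areas = coil_mesh.triangle_areas()
    cent = coil_mesh.triangle_centroids()
    nf = coil_mesh.n_faces

    # pairwise <1/R> kernel weighted by areas
    diff = cent[:, None, :] - cent[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    G = (areas[:, None] * areas[None, :]) / dist

    # refine near pairs: subdivide both triangles into 4
    h = np.sqrt(areas)
    near = dist < near_factor * (h[:, None] + h[None, :])
    iu, ju = np.nonzero(np.triu(near, k=1))
    if len(iu):
        v = coil_mesh.vertices[coil_mesh.faces]
        a, b, c = v[:, 0], v[:, 1], v[:, 2]
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        sub_cent = np.stack(
            [
                (a + ab + ca) / 3,
                (ab + b + bc) / 3,
                (ca + bc + c) / 3,
                (ab + bc + ca) / 3,
            ],
            axis=1,
        )  # (nf, 4, 3)
        d = np.linalg.norm(
            sub_cent[iu][:, :, None, :] - sub_cent[ju][:, None, :, :], axis=3
        )  # (npair, 4, 4)
        val = (areas[iu] / 4) * (areas[ju] / 4) * (1.0 / d).sum(axis=(1, 2))
        G[iu, ju] = val
        G[ju, iu] = val

    np.fill_diagonal(G, _triangle_self_inv_distance(coil_mesh) * areas**2)

    D = _hat_current_basis(coil_mesh)  # (nf, 3corner, 3xyz)
    # assemble current maps per Cartesian axis: C_axis (nf, n_interior) sparse
    from scipy.sparse import coo_matrix

    L = np.zeros((len(interior), len(interior)))
    inv = -np.ones(coil_mesh.n_vertices, dtype=int)
    inv[interior] = np.arange(len(interior))
    for axis in range(3):
        rows = np.repeat(np.arange(nf), 3)
        cols = inv[coil_mesh.faces.ravel()]
        vals = D[:, :, axis].ravel()
        keep = cols >= 0
        C = coo_matrix(
            (vals[keep], (rows[keep], cols[keep])), shape=(nf, len(interior))
        ).tocsr()
        GC = G @ C.toarray()
        L += C.T @ GC
    L *= MU0 / (4.0 * np.pi)
    L = 0.5 * (L + L.T)
    return InductanceMatrix(matrix=L, interior_idx=interior)


def _segment_neumann(
    s1: np.ndarray, e1: np.ndarray, s2: np.ndarray, e2: np.ndarray, n_gauss: int = 8
) -> np.ndarray:
    """Neumann double line integral between segment sets (vectorized pairs)."""
    from numpy.polynomial.legendre import leggauss

    x, wx = leggauss(n_gauss)
    t = 0.5 * (x + 1.0)
    w = 0.5 * wx
    d1 = e1 - s1  # (n, 3)
    d2 = e2 - s2
    p1 = s1[:, None, :] + t[None, :, None] * d1[:, None, :]  # (n, g, 3)
    p2 = s2[:, None, :] + t[None, :, None] * d2[:, None, :]
    R = np.linalg.norm(p1[:, :, None, :] - p2[:, None, :, :], axis=3)  # (n, g, g)
    ww = w[:, None] * w[None, :]
    dot = np.einsum("nj,nj->n", d1, d2)
    return dot * np.einsum("gh,ngh->n", ww, 1.0 / R)


def winding_inductance(w: WindingPath, n_gauss: int = 8, chunk: int = 2_000_000) -> float:
    """Total self-inductance (H) of a series winding via the Neumann formula.

    Mutual terms between distinct wire segments use Gauss-Legendre quadrature
    of the double line integral; each segment's own contribution uses the
    thin-wire closed form ``mu0 l/(2 pi) (ln(2 l / a) - 1)`` with ``a`` the
    wire radius (external inductance; DC internal inductance neglected).
    """
    if w.n_loops < 1:
        raise ValueError("winding must contain at least one loop")
    if w.wire_diameter <= 0:
        raise ValueError("wire diameter must be positive")
    starts, ends, cur = w.segments()
    sign = np.sign(cur)
    n = len(starts)
    a = w.wire_diameter / 2.0
    lens = np.linalg.norm(ends - starts, axis=1)
    ok = lens > 0
    starts, ends, sign, lens = starts[ok], ends[ok], sign[ok], lens[ok]
    n = len(starts)

    L_self = (MU0 / (2.0 * np.pi)) * np.sum(lens * (np.log(2.0 * lens / a) - 1.0))

    iu, ju = np.triu_indices(n, k=1)
    total = 0.0
    step = max(1, chunk // (n_gauss * n_gauss))
    for lo in range(0, len(iu), step):
        i = iu[lo : lo + step]
        j = ju[lo : lo + step]
        vals = _segment_neumann(starts[i], ends[i], starts[j], ends[j], n_gauss)
        total += float(np.sum(sign[i] * sign[j] * vals))
    L_mutual = (MU0 / (4.0 * np.pi)) * 2.0 * total
    return L_self + L_mutual


def winding_resistance(
    w: WindingPath,
    resistivity: float = COPPER_RESISTIVITY,
    wire_area: float | None = None,
) -> float:
    """DC resistance (ohm): litz wire treated as solid copper of equal OD."""
    if w.wire_diameter <= 0:
        raise ValueError("wire diameter must be positive")
    if wire_area is None:
        wire_area = np.pi * (w.wire_diameter / 2.0) ** 2
    return resistivity * w.total_length() / wire_area
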