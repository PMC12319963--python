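"""Meshes, coordinate frames, and the winding-path data model.

Coordinate frame convention
---------------------------
All geometry lives in a coil-centred frame: the origin sits at the centre of
the rectangular coil former, the x/y axes span the coil plane, and the head
model is placed on the -z side.  A spherical cortex model of radius ``r`` at
standoff ``d`` (closest cortex-to-plane distance) therefore has its centre at
``(0, 0, -(d + r))``.  Stimulus orientation angles are measured in the coil
plane, counterclockwise when viewed from +z, with 0 deg along +x (the peak
E-field direction of the bottom coil).

Lengths are SI metres internally; file interfaces (winding JSON) use mm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

WINDING_SCHEMA = "mtms-winding/1"

__all__ = [
    "TriMesh",
    "SphericalHeadModel",
    "CoilPlane",
    "WindingPath",
    "make_sphere_mesh",
    "make_plane_mesh",
    "read_mesh",
    "read_winding",
    "write_winding",
    "WindingParseError",
]


class WindingParseError(ValueError):
    """Raised when a winding JSON file is malformed."""


@dataclass
class TriMesh:
    """Triangular surface mesh (vertices in metres)."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int
    boundary_mask: np.ndarray | None = None  # True for boundary vertices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("faces index invalid vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def triangle_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norms = np.linalg.norm(cross, axis=1)
        return cross / norms[:, None]

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def euler_characteristic(self) -> int:
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def boundary_vertices(self) -> np.ndarray:
        """Indices of vertices on open boundaries (edges used by one face)."""
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        open_edges = uniq[counts == 1]
        return np.unique(open_edges)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )


@dataclass
class SphericalHeadModel:
    """Spherically symmetric volume conductor with a cortex evaluation mesh.

    The induced E-field in such a conductor is independent of the radial
    conductivity profile, so no conductivity value is stored.
    """

    center: np.ndarray  # (3,) m
    radius: float  # m
    cortex_mesh: TriMesh

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        r = np.linalg.norm(self.cortex_mesh.vertices - self.center, axis=1)
        if np.max(np.abs(r - self.radius)) > 1e-6 * self.radius:
            raise ValueError("cortex mesh vertices are not on the sphere surface")

    @classmethod
    def at_standoff(
        cls,
        radius: float,
        standoff: float,
        n_target_vertices: int = 2562,
        cap_deg: float | None = None,
    ) -> "SphericalHeadModel":
        """Head sphere placed below the coil plane at the given standoff.

        ``cap_deg`` optionally restricts the evaluation mesh to the spherical
        cap (half-angle in degrees, measured from the point closest to the
        coil) facing the coil; ``None`` keeps the full sphere.
        """
        center = np.array([0.0, 0.0, -(standoff + radius)])
        mesh = make_sphere_mesh(radius, n_target_vertices)
        verts = mesh.vertices + center
        faces = mesh.faces
        if cap_deg is not None:
            # keep faces whose vertices all lie within the cap around +z
            cosang = (mesh.vertices[:, 2] / radius).clip(-1, 1)
            keep_v = np.degrees(np.arccos(cosang)) <= cap_deg
            keep_f = keep_v[faces].all(axis=1)
            faces = faces[keep_f]
            used = np.unique(faces)
            remap = -np.ones(len(verts), dtype=int)
            remap[used] = np.arange(len(used))
            verts = verts[used]
            faces = remap[faces]
        return cls(center=center, radius=radius, cortex_mesh=TriMesh(verts, faces))


@dataclass
class CoilPlane:
    """Rectangular coil former carrying the surface current."""

    length: float  # m, along x
    width: float  # m, along y
    standoff: float  # m, plane to closest cortex point along -z
    mesh: TriMesh = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("plane dimensions must be positive")
        if self.mesh is None:
            self.mesh = make_plane_mesh(self.length, self.width, 1953)


@dataclass
class WindingPath:
    """Discrete wire loops realizing a surface current.

    Each loop is a closed polyline (first point repeated last), carries the
    same current magnitude ``current_per_turn`` with sign ``polarity``, and is
    assigned to a physical winding ``layer`` (two layers of litz wire in the
    manufactured coils, vertically offset by one wire diameter).
    """

    loops: list  # list of (k, 3) float arrays, closed
    polarities: list  # +1 / -1 per loop
    layers: list  # int per loop
    wire_diameter: float  # m
    current_per_turn: float = 1.0  # A per unit stream-function step

    def __post_init__(self) -> None:
        self.loops = [np.asarray(l, dtype=float) for l in self.loops]
        if not (len(self.loops) == len(self.polarities) == len(self.layers)):
            raise ValueError("loops, polarities and layers must have equal length")
        if self.wire_diameter <= 0:
            raise ValueError("wire_diameter must be positive")
        for l in self.loops:
            if l.ndim != 2 or l.shape[1] != 3 or len(l) < 4:
                raise ValueError("each loop must be a (k>=4, 3) polyline")
            if not np.allclose(l[0], l[-1], atol=1e-12):
                raise ValueError("loops must be closed (first point == last point)")

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    def total_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(l, axis=0), axis=1).sum() for l in self.loops)
        )

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All wire segments as (starts, ends, signed_current) arrays."""
        starts, ends, cur = [], [], []
        for loop, pol in zip(self.loops, self.polarities):
            starts.append(loop[:-1])
            ends.append(loop[1:])
            cur.append(np.full(len(loop) - 1, pol * self.current_per_turn))
        return np.vstack(starts), np.vstack(ends), np.concatenate(cur)


# ---------------------------------------------------------------------------
# Mesh constructors
# ---------------------------------------------------------------------------


def make_sphere_mesh(radius: float, n_target_vertices: int = 2562) -> TriMesh:
    """Icosphere with vertex count closest to the target.

    Successive icosahedron subdivisions give 12, 42, 162, 642, 2562, 10242, ...
    vertices (10*4**k + 2); the subdivision level nearest ``n_target_vertices``
    is chosen and every vertex is projected exactly onto the sphere.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_target_vertices < 12:
        raise ValueError("n_target_vertices must be at least 12")
    counts = [10 * 4**k + 2 for k in range(9)]
    k = int(np.argmin([abs(c - n_target_vertices) for c in counts]))
    ico = trimesh.creation.icosphere(subdivisions=k, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float)
    verts = radius * verts / np.linalg.norm(verts, axis=1)[:, None]
    return TriMesh(verts, np.asarray(ico.faces, dtype=int))


def make_plane_mesh(length: float, width: float, n_target_vertices: int = 1953) -> TriMesh:
    """Near-uniform triangulated rectangle in the z=0 plane, centred at origin.

    A structured nx-by-ny grid is used with the aspect ratio matched to the
    rectangle so the triangles are near-isotropic; boundary vertices are
    flagged in ``boundary_mask``.
    """
    if length <= 0 or width <= 0:
        raise ValueError("rectangle dimensions must be positive")
    if n_target_vertices < 4:
        raise ValueError("need at least 4 vertices")
    # nx/ny ~ length/width and nx*ny ~ target
    ny = max(2, round(math.sqrt(n_target_vertices * width / length)))
    nx = max(2, round(n_target_vertices / ny))
    xs = np.linspace(-length / 2, length / 2, nx)
    ys = np.linspace(-width / 2, width / 2, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = (i + 1) * ny + j + 1
            d = i * ny + j + 1
            # alternate the quad diagonal for isotropy
            if (i + j) % 2 == 0:
                faces.append([a, b, c])
                faces.append([a, c, d])
            else:
                faces.append([a, b, d])
                faces.append([b, c, d])
    faces = np.asarray(faces, dtype=int)

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    boundary = (
        (ii == 0) | (ii == nx - 1) | (jj == 0) | (jj == ny - 1)
    ).ravel()
    return TriMesh(verts, faces, boundary_mask=boundary)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path) -> TriMesh:
    """Read an STL/OBJ/PLY mesh, deduplicating vertices at 1e-9 m tolerance."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    loaded = trimesh.load_mesh(str(path), process=False)
    if isinstance(loaded, trimesh.Scene):
        loaded = loaded.to_mesh()
    verts = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=int)
    # dedup at fixed 1e-9 m tolerance
    keys = np.round(verts / 1e-9).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    verts = verts[np.sort(first)]
    faces = rank[inverse][faces]
    return TriMesh(verts, faces)


def _to_mm_exact(x: np.ndarray) -> np.ndarray:
    """Convert metres to mm such that mm/1e3 reproduces x bit-exactly.

    x*1e3 is correctly rounded but not always an exact preimage of x under
    division by 1e3; where it is not, the neighbouring representable value is
    used instead (off by at most one ulp in the stored mm figure).
    """
    x = np.asarray(x, dtype=float)
    mm = x * 1e3
    bad = (mm / 1e3) != x
    if np.any(bad):
        for direction in (np.inf, -np.inf):
            cand = mm.copy()
            for _ in range(4):
                cand = np.nextafter(cand, direction)
                fix = bad & ((cand / 1e3) == x)
                mm[fix] = cand[fix]
                bad &= ~fix
    return mm


def write_winding(path: str | Path, w: WindingPath) -> None:
    """Write a winding path as versioned JSON (coordinates in mm)."""
    obj = {
        "schema": WINDING_SCHEMA,
        "wire_diameter_mm": float(_to_mm_exact(w.wire_diameter)),
        "current_per_turn_A": w.current_per_turn,
        "loops": [
            {
                "polarity": int(pol),
                "layer": int(lay),
                "points_mm": _to_mm_exact(loop).tolist(),
            }
            for loop, pol, lay in zip(w.loops, w.polarities, w.layers)
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_winding(path: str | Path) -> WindingPath:
    """Read a winding-path JSON written by :func:`write_winding`.

    Round-trips bit-exactly: JSON serialization of Python floats uses
    shortest-repr encoding, which is lossless for float64.
    """
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise WindingParseError(
            f"{path}: invalid JSON at line {err.lineno}: {err.msg}"
        ) from err
    if not isinstance(obj, dict) or obj.get("schema") != WINDING_SCHEMA:
        raise WindingParseError(f"{path}: missing or unknown schema (expected {WINDING_SCHEMA})")
    for key in ("wire_diameter_mm", "loops"):
        if key not in obj:
            raise WindingParseError(f"{path}: missing required field '{key}'")
    loops, pols, lays = [], [], []
    for i, entry in enumerate(obj["loops"]):
        for key in ("polarity", "layer", "points_mm"):
            if key not in entry:
                raise WindingParseError(f"{path}: loop {i} missing field '{key}'")
        loops.append(np.asarray(entry["points_mm"], dtype=float) / 1e3)
        pols.append(int(entry["polarity"]))
        lays.append(int(entry["layer"]))
    return WindingPath(
        loops=loops,
        polarities=pols,
        layers=lays,
        wire_diameter=float(obj["wire_diameter_mm"]) / 1e3,
        current_per_turn=float(obj.get("current_per_turn_A", 1.0)),
    )
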