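"""Two-coil array design pipeline.

The array is designed to reproduce, with planar surface currents, the
E-field of a small commercial figure-of-eight coil at two orientations
(0 and 90 degrees) on a 13.7-mm-radius spherical model of the rat cortex:

1. Capture the reference fields of the figure-of-eight model at both
   orientations on the cortex mesh.
2. For each orientation, find the minimum-energy stream function on a
   rectangular coil former (bottom former 15 mm, top former 20 mm from the
   cortical surface) whose field matches the reference peak exactly and the
   full reference map within a relative tolerance, subject to a wire-density
   bound on the surface-current magnitude.
3. Orthogonalize the two stream functions by singular value decomposition.
4. Discretize each component into wire loops by contouring the stream
   function at a fixed number of isolines.

The result is two orthogonal figure-of-eight windings (seven turns per wing
at the default 14 isolines) ready for inductance/resistance/focality
reporting and electronic orientation control.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from . import efield as ef
from ._qp import InfeasibleProblemError, solve_qp
from .geometry import CoilPlane, SphericalHeadModel, TriMesh, WindingPath, make_plane_mesh

__all__ = [
    "StreamFunction",
    "DesignSpec",
    "Figure8Spec",
    "DesignReport",
    "reference_field",
    "minimum_energy_stream",
    "svd_decompose",
    "discretize_isolines",
    "design_two_coil_array",
    "InfeasibleDesignError",
    "DiscretizationError",
]


class InfeasibleDesignError(RuntimeError):
    """No stream function satisfies the design constraints."""


class DiscretizationError(RuntimeError):
    """Isoline contouring produced an open contour (stream not boundary-zero)."""


@dataclass
class StreamFunction:
    """Per-vertex stream function on a coil mesh (boundary values zero).

    Isolines of the stream function are current paths; the magnitude of its
    surface gradient is the surface current density.
    """

    values: np.ndarray  # (n_vertices,) A
    mesh: TriMesh
    plane_z: float = 0.0
    energy: float | None = None  # 0.5 psi' L psi at solve time
    kkt_residual: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError("one stream value per mesh vertex required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stream function must be finite")

    def interior(self, interior_idx: np.ndarray) -> np.ndarray:
        return self.values[interior_idx]


@dataclass
class Figure8Spec:
    """Planar figure-of-eight reference coil approximation.

    Modelled as two coplanar circular wings with opposing currents; turn
    radii are spaced linearly from the inner radius to the wing outer
    radius.  Defaults approximate a 35-mm commercial rodent coil.
    """

    outer_diameter: float = 0.035  # m
    n_turns_per_wing: int = 10
    inner_radius: float = 0.005  # m
    segments_per_turn: int = 64

    def winding(self, orientation_deg: float = 0.0, plane_z: float = 0.0) -> WindingPath:
        """Wire loops of the reference coil at the given in-plane rotation.

        At 0 degrees the wings are stacked along y so the peak E-field under
        the wing junction points along +x.
        """
        r_out = self.outer_diameter / 2.0
        radii = np.linspace(self.inner_radius, r_out, self.n_turns_per_wing)
        th = np.linspace(0.0, 2.0 * np.pi, self.segments_per_turn + 1)
        c, s = np.cos(np.radians(orientation_deg)), np.sin(np.radians(orientation_deg))
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        loops, pols, lays = [], [], []
        for wing_sign, wing_y in ((+1, r_out), (-1, -r_out)):
            for r in radii:
                pts = np.column_stack(
                    [r * np.cos(th), wing_y + r * np.sin(th), np.full_like(th, plane_z)]
                )
                pts[-1] = pts[0]
                loops.append(pts @ rot.T)
                pols.append(wing_sign)
                lays.append(0)
        return WindingPath(loops, pols, lays, wire_diameter=1e-3)


@dataclass
class DesignSpec:
    """Inputs of one minimum-energy stream-function optimization."""

    target_field: ef.EFieldMap
    tolerance: float  # relative field deviation, in (0, 1)
    density_bound: float  # max surface-current magnitude (A/m); np.inf allowed
    plane: CoilPlane

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance < 1.0:
            raise ValueError("tolerance must be in (0, 1)")
        if not self.density_bound > 0:
            raise ValueError("density_bound must be positive")


def reference_field(
    model: Figure8Spec,
    head: SphericalHeadModel,
    points: np.ndarray,
    orientation_deg: float,
    plane_z: float = 0.0,
) -> ef.EFieldMap:
    """E-field of the reference figure-of-eight coil at a given orientation.

    The sign of the coil current is fixed so the peak field at 0 degrees
    points along +x (and rotates with the coil).
    """
    w = model.winding(orientation_deg, plane_z=plane_z)
    m = ef.efield_segments(w, head, points)
    # orient: peak E along the rotated +x axis
    idx = int(np.argmax(m.magnitudes))
    want = np.array(
        [np.cos(np.radians(orientation_deg)), np.sin(np.radians(orientation_deg))]
    )
    if m.vectors[idx, :2] @ want < 0:
        m = m.scaled(-1.0)
    m.source_id = f"figure8@{orientation_deg:g}deg"
    return m


def _density_rows(mesh: TriMesh, interior: np.ndarray):
    """Per-triangle in-plane surface-current components as rows over interior
    stream values (x and y components; the mesh is planar)."""
    from scipy.sparse import coo_matrix

    D = ef._hat_current_basis(mesh)
    nf = mesh.n_faces
    inv = -np.ones(mesh.n_vertices, dtype=int)
    inv[interior] = np.arange(len(interior))
    mats = []
    for axis in (0, 1):
        rows = np.repeat(np.arange(nf), 3)
        cols = inv[mesh.faces.ravel()]
        vals = D[:, :, axis].ravel()
        keep = cols >= 0
        mats.append(
            coo_matrix(
                (vals[keep], (rows[keep], cols[keep])), shape=(nf, len(interior))
            ).toarray()
        )
    return np.vstack(mats)


def minimum_energy_stream(
    spec: DesignSpec,
    basis: ef.BasisMatrix,
    L: ef.InductanceMatrix,
    eps: float = 1e-8,
    max_iter: int = 20000,
    warm_start: StreamFunction | None = None,
) -> StreamFunction:
    """Minimum-energy stream function reproducing the target field.

    Minimizes the magnetic energy ``0.5 psi' L psi`` subject to (a) the field
    at the target's peak point equal to the target peak vector, (b) every
    field sample within ``tolerance * |E_peak|`` of the target per Cartesian
    component, and (c) the in-plane surface-current components bounded by
    the wire-density limit.  Raises :class:`InfeasibleDesignError` naming the
    binding constraint family if no stream function satisfies them.
    """
    t = spec.target_field.vectors.reshape(-1)
    if not np.any(t != 0.0):
        return StreamFunction(
            np.zeros(basis.mesh.n_vertices), basis.mesh, energy=0.0, kkt_residual=0.0
        )
    norms = spec.target_field.magnitudes
    peak = int(np.argmax(norms))
    e_peak = norms[peak]

    B = basis.matrix / e_peak
    th = t / e_peak
    ni = B.shape[1]

    # variable scaling: least-squares field fit sets the natural psi scale,
    # keeping the ADMM iteration well conditioned
    psi_ls, *_ = np.linalg.lstsq(B, th, rcond=None)
    xscale = max(float(np.max(np.abs(psi_ls))), 1e-12)

    # constraint stack: peak equality (3 rows), field tolerance band, density
    rows_eq = B[3 * peak : 3 * peak + 3]
    b_eq = th[3 * peak : 3 * peak + 3]
    blocks_A = [rows_eq, B]
    blocks_l = [b_eq, th - spec.tolerance]
    blocks_u = [b_eq, th + spec.tolerance]
    n_density = 0
    if np.isfinite(spec.density_bound):
        Dxy = _density_rows(basis.mesh, basis.interior_idx)
        n_density = Dxy.shape[0]
        blocks_A.append(Dxy)
        blocks_l.append(np.full(n_density, -spec.density_bound))
        blocks_u.append(np.full(n_density, spec.density_bound))

    A = np.vstack(blocks_A) * xscale
    l = np.concatenate(blocks_l)
    u = np.concatenate(blocks_u)

    P = L.matrix * xscale**2
    pscale = float(np.trace(P)) / P.shape[0]
    x0 = None
    if warm_start is not None:
        x0 = warm_start.values[basis.interior_idx] / xscale
    try:
        res = solve_qp(
            P / pscale, np.zeros(ni), A, l, u, eps=eps, max_iter=max_iter, x0=x0
        )
    except InfeasibleProblemError as err:
        m_eq, m_field = 3, 3 * len(norms)
        fam = "peak equality"
        if err.worst_row is not None:
            if err.worst_row >= m_eq + m_field:
                fam = "wire-density bound"
            elif err.worst_row >= m_eq:
                fam = "field tolerance band"
        raise InfeasibleDesignError(
            f"design constraints infeasible; binding family: {fam}"
        ) from err

    logger.info(
        "QP: %d iterations, KKT residual %.2e, polished=%s",
        res.iterations, res.kkt_residual, res.polished,
    )
    psi = np.zeros(basis.mesh.n_vertices)
    psi[basis.interior_idx] = res.x * xscale
    return StreamFunction(
        psi,
        basis.mesh,
        plane_z=float(basis.mesh.vertices[0, 2]),
        energy=float(0.5 * res.x @ P @ res.x),
        kkt_residual=res.kkt_residual,
    )


def svd_decompose(streams: list[StreamFunction]) -> list[StreamFunction]:
    """Orthogonal stream-function components via singular value decomposition.

    Returns the left singular vectors scaled by their singular values, in
    descending order.  Inputs must share a mesh parameterization (vertex
    count); each output keeps the plane of the corresponding input.
    """
    if len(streams) < 1:
        raise ValueError("need at least one stream function")
    n = streams[0].mesh.n_vertices
    for s in streams:
        if s.mesh.n_vertices != n:
            raise ValueError("stream functions live on mismatched meshes")
    X = np.column_stack([s.values for s in streams])
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    out = []
    for k in range(len(streams)):
        out.append(
            StreamFunction(
                U[:, k] * S[k], streams[k].mesh, plane_z=streams[k].plane_z
            )
        )
    return out


# ---------------------------------------------------------------------------
# Isoline discretization (marching triangles)
# ---------------------------------------------------------------------------


def _contour_loops(mesh: TriMesh, values: np.ndarray, level: float):
    """Closed contour polylines of a vertex field at one level."""
    v = mesh.vertices
    f = mesh.faces
    vals = values
    # nudge the level off any vertex value to avoid degenerate crossings
    rng = float(np.ptp(vals)) or 1.0
    while np.any(np.abs(vals - level) < 1e-12 * rng):
        level = level + 1e-9 * rng

    # crossing points per (sorted) edge, and crossing edges per face
    edge_pts: dict[tuple[int, int], np.ndarray] = {}
    face_edges: list[list[tuple[int, int]]] = []
    for tri in f:
        crossings = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            va, vb = vals[a] - level, vals[b] - level
            if va * vb < 0:
                key = (min(a, b), max(a, b)) if a < b else (b, a)
                if key not in edge_pts:
                    t = va / (va - vb)
                    edge_pts[key] = v[a] + t * (v[b] - v[a])
                crossings.append(key)
        face_edges.append(crossings)

    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, ce in enumerate(face_edges):
        for key in ce:
            edge_faces.setdefault(key, []).append(fi)

    loops = []
    visited = set()
    for start_face, ce in enumerate(face_edges):
        if len(ce) != 2 or start_face in visited:
            continue
        loop_keys = [ce[0]]
        face = start_face
        enter = ce[0]
        while True:
            visited.add(face)
            e1, e2 = face_edges[face]
            exit_key = e2 if enter == e1 else e1
            nxt = [g for g in edge_faces[exit_key] if g != face]
            if not nxt:
                raise DiscretizationError(
                    "open contour reached the mesh boundary; stream function is "
                    "not zero on the boundary"
                )
            if exit_key == loop_keys[0]:
                break  # closed
            loop_keys.append(exit_key)
            face = nxt[0]
            enter = exit_key
        pts = np.array([edge_pts[k] for k in loop_keys])
        if len(pts) >= 3:
            pts = np.vstack([pts, pts[:1]])
            loops.append(pts)
    return loops


def _ensure_ccw(loop: np.ndarray) -> np.ndarray:
    x, y = loop[:, 0], loop[:, 1]
    signed = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    return loop[::-1].copy() if signed < 0 else loop


def discretize_isolines(
    s: StreamFunction,
    n_isolines: int = 14,
    wire_diameter: float = 1.7e-3,
    two_layers: bool = True,
) -> WindingPath:
    """Wire loops from a stream function by equal-bin isoline contouring.

    Contour levels sit at the midpoints of ``n_isolines`` equal-width bins
    spanning [min psi, max psi]; each contour is a closed loop carrying
    ``current_per_turn`` equal to the bin width, with polarity the sign of
    the local stream function.  Loops are assigned to two alternating layers
    offset by one wire diameter (the physical two-layer litz winding).
    """
    if n_isolines < 1:
        raise ValueError("need at least one isoline")
    vals = s.values
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("stream function is constant; nothing to contour")
    width = (hi - lo) / n_isolines
    levels = lo + (np.arange(n_isolines) + 0.5) * width

    loops, pols, lays = [], [], []
    for level in levels:
        for loop in _contour_loops(s.mesh, vals, level):
            loops.append(_ensure_ccw(loop))
            pols.append(1 if level > 0 else -1)
    # deterministic ordering: by centroid x, then y, then descending |level|
    order = sorted(
        range(len(loops)),
        key=lambda i: (
            round(loops[i][:-1, 0].mean(), 9),
            round(loops[i][:-1, 1].mean(), 9),
            -abs(pols[i]),
        ),
    )
    loops = [loops[i] for i in order]
    pols = [pols[i] for i in order]
    # the two layers straddle the nominal winding plane symmetrically, one
    # wire diameter apart, so the effective source plane stays at the
    # designed standoff
    for i, loop in enumerate(loops):
        layer = i % 2 if two_layers else 0
        lays.append(layer)
        if two_layers:
            loop = loop.copy()
            loop[:, 2] += (layer - 0.5) * wire_diameter
            loops[i] = loop
    return WindingPath(
        loops, pols, lays, wire_diameter=wire_diameter, current_per_turn=width
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class DesignReport:
    """Per-coil summary of the designed array."""

    focality_perp_mm: dict
    focality_par_mm: dict
    inductance_uH: dict
    resistance_mOhm: dict
    n_loops: dict
    peak_dirs: dict
    peak_mags: dict  # V/m per A/s, on the design sphere
    stream_energy: dict


def design_two_coil_array(
    sphere_radius: float = 0.0137,
    n_sphere_vertices: int = 2562,
    plane_length: float = 0.19,
    plane_width: float = 0.095,
    n_plane_vertices: int = 1953,
    standoffs: tuple[float, float] = (0.015, 0.020),
    n_isolines: int = 14,
    tolerance: float = 0.10,
    wire_diameter: float = 1.7e-3,
    figure8: Figure8Spec | None = None,
    compute_report: bool = True,
) -> tuple[WindingPath, WindingPath, DesignReport | None]:
    """Run the full design pipeline with the array's default parameters.

    The bottom coil former sits at ``standoffs[0]`` and the top former at
    ``standoffs[1]`` from the cortical surface; the reference coil is placed
    at the bottom standoff for both orientations.  Returns the two windings
    (bottom, top) and, optionally, a report of focality, inductance and
    resistance per coil.
    """
    figure8 = figure8 or Figure8Spec()
    head = SphericalHeadModel.at_standoff(
        sphere_radius, standoffs[0], n_sphere_vertices
    )
    pts = head.cortex_mesh.vertices

    targets = [
        reference_field(figure8, head, pts, 0.0, plane_z=0.0),
        reference_field(figure8, head, pts, 90.0, plane_z=0.0),
    ]

    streams = []
    basis_by_coil = []
    for target, standoff in zip(targets, standoffs):
        z = standoff - standoffs[0]
        mesh2d = make_plane_mesh(plane_length, plane_width, n_plane_vertices)
        mesh = TriMesh(
            mesh2d.vertices + np.array([0.0, 0.0, z]),
            mesh2d.faces,
            boundary_mask=mesh2d.boundary_mask,
        )
        plane = CoilPlane(plane_length, plane_width, standoff, mesh)
        t0 = _time.time()
        basis = ef.efield_basis(mesh, head, pts)
        logger.info("field basis at standoff %.0f mm: %.1f s", standoff * 1e3, _time.time() - t0)
        t0 = _time.time()
        L = ef.inductance_matrix(mesh)
        logger.info("inductance matrix: %.1f s", _time.time() - t0)
        # two-pass wire-density rule: the bound depends on current_per_turn,
        # which is only known once the stream range is known
        spec1 = DesignSpec(target, tolerance, np.inf, plane)
        t0 = _time.time()
        s1 = minimum_energy_stream(spec1, basis, L)
        bound = float(np.ptp(s1.values)) / n_isolines / wire_diameter
        spec2 = DesignSpec(target, tolerance, bound, plane)
        s2 = minimum_energy_stream(spec2, basis, L, warm_start=s1)
        logger.info(
            "stream optimization at standoff %.0f mm: %.1f s (KKT %.1e)",
            standoff * 1e3, _time.time() - t0, s2.kkt_residual,
        )
        streams.append(s2)
        basis_by_coil.append(basis)

    comps = svd_decompose(streams)
    # pair each SVD component with the input stream it correlates with most
    # strongly (singular-value order need not match the bottom/top order)
    corr = np.abs(
        np.array(
            [[c.values @ s.values for s in streams] for c in comps]
        )
    )
    if corr[0, 0] * corr[1, 1] < corr[0, 1] * corr[1, 0]:
        comps = [comps[1], comps[0]]
    comps = [
        StreamFunction(c.values, s.mesh, plane_z=s.plane_z)
        for c, s in zip(comps, streams)
    ]
    # sign convention: component k's field peak along the target-k direction
    windings = []
    for k, (comp, basis, target) in enumerate(zip(comps, basis_by_coil, targets)):
        m = basis.field_of(comp.values[basis.interior_idx])
        idx = int(np.argmax(m.magnitudes))
        tdir = target.vectors[int(np.argmax(target.magnitudes))]
        if m.vectors[idx] @ tdir < 0:
            comp = StreamFunction(-comp.values, comp.mesh, plane_z=comp.plane_z)
        windings.append(
            discretize_isolines(comp, n_isolines=n_isolines, wire_diameter=wire_diameter)
        )
    bottom, top = windings

    report = None
    if compute_report:
        from .metrics import focality_width, geodesic_profile, peak_field

        report = DesignReport({}, {}, {}, {}, {}, {}, {}, {})
        for name, w, s in (("bottom", bottom, comps[0]), ("top", top, comps[1])):
            t0 = _time.time()
            m = ef.efield_segments(w, head, pts)
            logger.info("%s-coil field + metrics: %.1f s", name, _time.time() - t0)
            _, pdir, pmag = peak_field(m)
            report.peak_dirs[name] = pdir
            report.peak_mags[name] = pmag
            report.focality_perp_mm[name] = (
                focality_width(geodesic_profile(m, head, "perpendicular")) * 1e3
            )
            report.focality_par_mm[name] = (
                focality_width(geodesic_profile(m, head, "parallel")) * 1e3
            )
            report.inductance_uH[name] = ef.winding_inductance(w) * 1e6
            report.resistance_mOhm[name] = ef.winding_resistance(w) * 1e3
            report.n_loops[name] = w.n_loops
            report.stream_energy[name] = s.energy
    return bottom, top, report
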