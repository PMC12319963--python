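"""Independent numerical oracles used only by the test suite.

These deliberately take different routes than the package implementation:

* ``bem_efield_segments`` -- surface-charge boundary-element solution of the
  quasi-static problem (primary -dA/dt from an analytic segment integral plus
  the field of a single-layer charge solved by collocation), instead of the
  closed-form spherical-conductor reciprocity formula.
* ``neumann_polyline_inductance`` -- brute-force Neumann double line integral
  on explicit polylines with dense midpoint subdivision.
* ``kkt_equality_qp`` -- dense KKT solve of an equality-constrained QP.
"""

from __future__ import annotations

import numpy as np

MU0 = 4e-7 * np.pi


def vector_potential_per_current(starts, ends, signs, pts):
    """A/I at pts for unit current in straight segments (analytic integral)."""
    starts = np.asarray(starts, float)
    ends = np.asarray(ends, float)
    signs = np.asarray(signs, float)
    pts = np.asarray(pts, float)
    seg = ends - starts
    L = np.linalg.norm(seg, axis=1)
    u = seg / L[:, None]
    A = np.zeros((len(pts), 3))
    for p_idx, r in enumerate(pts):
        d_s = np.linalg.norm(r - starts, axis=1)
        d_e = np.linalg.norm(r - ends, axis=1)
        t0 = np.einsum("ij,ij->i", r - starts, u)
        # integral of 1/|r - (s + t u)| dt from 0 to L
        val = np.log((L - t0 + d_e) / (-t0 + d_s))
        A[p_idx] = (MU0 / (4 * np.pi)) * np.sum((signs * val)[:, None] * u, axis=0)
    return A


def bem_efield_segments(winding, head, pts):
    """Total E per unit dI/dt via a surface-charge BEM on the head sphere."""
    mesh = head.cortex_mesh
    verts = mesh.vertices
    center = head.center
    normals_v = (verts - center) / np.linalg.norm(verts - center, axis=1)[:, None]

    # vertex weights: one third of adjacent triangle areas
    areas = mesh.triangle_areas()
    w = np.zeros(len(verts))
    for k in range(3):
        np.add.at(w, mesh.faces[:, k], areas / 3.0)

    starts, ends, cur = winding.segments()
    signs = np.sign(cur)

    # primary field -dA/dt per unit dI/dt at surface vertices
    Ep_surf = -vector_potential_per_current(starts, ends, signs, verts)
    g = np.einsum("ij,ij->i", Ep_surf, normals_v)

    # collocation matrix of the principal-value normal-derivative operator
    diff = verts[:, None, :] - verts[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    K = -np.einsum("ik,ijk->ij", normals_v, diff) / (4 * np.pi * dist**3) * w[None, :]
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -0.5 - K.sum(axis=1))
    M = K + 0.5 * np.eye(len(verts))
    q, *_ = np.linalg.lstsq(M, g, rcond=None)

    # secondary field -grad V of the single layer, at interior points
    pts = np.asarray(pts, float)
    diffp = pts[:, None, :] - verts[None, :, :]
    dp = np.linalg.norm(diffp, axis=2)
    Esec = np.einsum("j,ijk->ik", q * w, diffp / (4 * np.pi * dp**3)[:, :, None])
    Ep = -vector_potential_per_current(starts, ends, signs, pts)
    return Ep + Esec


def neumann_polyline_inductance(loops, signs, wire_radius, n_sub=8):
    """Neumann formula with dense midpoint subdivision (mutual terms) plus the
    thin-wire self term per original segment."""
    starts, ends, sgn = [], [], []
    self_L = 0.0
    for loop, s in zip(loops, signs):
        loop = np.asarray(loop, float)
        seg = np.diff(loop, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        keep = lens > 0
        self_L += (MU0 / (2 * np.pi)) * np.sum(
            lens[keep] * (np.log(2 * lens[keep] / wire_radius) - 1.0)
        )
        # subdivide for mutual quadrature
        for p0, d in zip(loop[:-1][keep], seg[keep]):
            for k in range(n_sub):
                starts.append(p0 + d * k / n_sub)
                ends.append(p0 + d * (k + 1) / n_sub)
                sgn.append(s)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    sgn = np.asarray(sgn, float)
    mids = 0.5 * (starts + ends)
    dl = ends - starts
    n = len(mids)
    dist = np.linalg.norm(mids[:, None, :] - mids[None, :, :], axis=2)
    dots = dl @ dl.T
    ss = np.outer(sgn, sgn)
    # exclude pairs of sub-segments belonging to the same original segment:
    # approximate by excluding near-collinear overlapping pairs via distance 0
    np.fill_diagonal(dist, np.inf)
    # identify same-parent pairs: consecutive indices within the same segment
    # sub-segment pairs within the same parent segment are already covered by
    # the parent's thin-wire self term
    parent = np.repeat(np.arange(n // n_sub), n_sub)
    same = parent[:, None] == parent[None, :]
    M = np.where(same, 0.0, ss * dots / dist)
    return self_L + (MU0 / (4 * np.pi)) * M.sum()


def kkt_equality_qp(P, A, b):
    """Solve min 0.5 x'Px s.t. Ax=b via the dense KKT system.

    Uses a least-squares solve so redundant (e.g. identically-zero)
    constraint rows do not make the system singular; the primal part is
    unique whenever P is positive definite.
    """
    n = P.shape[0]
    m = A.shape[0]
    K = np.block([[P, A.T], [A, np.zeros((m, m))]])
    rhs = np.concatenate([np.zeros(n), b])
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    return sol[:n]
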