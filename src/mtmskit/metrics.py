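"""Peak-field extraction, geodesic field profiles, focality and intensity.

Focality follows the TMS convention: the full width of the |E| profile at
1/sqrt(2) (71%) of its maximum, measured along great-circle geodesics on the
spherical cortex model through the peak, in the directions parallel and
perpendicular to the peak E-field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efield import EFieldMap
from .geometry import SphericalHeadModel

__all__ = [
    "FieldProfile",
    "peak_field",
    "geodesic_profile",
    "focality_width",
    "intensity_rising_phase",
    "UndefinedPeakError",
    "UnboundedWidthError",
]


class UndefinedPeakError(ValueError):
    """All-zero field: the peak location is undefined."""


class UnboundedWidthError(ValueError):
    """The profile never drops below the focality level on one side."""


@dataclass
class FieldProfile:
    """|E| sampled along a geodesic through the field peak.

    ``arclength`` is signed distance along the geodesic (m), zero at the
    peak; ``magnitudes`` the interpolated |E| samples; ``direction`` a label
    ("parallel" or "perpendicular" relative to the peak-E direction).
    """

    arclength: np.ndarray
    magnitudes: np.ndarray
    direction: str = ""

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")


def peak_field(m: EFieldMap) -> tuple[np.ndarray, np.ndarray, float]:
    """Peak location, tangential direction and magnitude of a field map.

    Ties are broken toward the smallest vertex index.
    """
    mags = m.magnitudes
    if not np.any(mags > 0):
        raise UndefinedPeakError("field is identically zero")
    idx = int(np.argmax(mags))  # argmax returns the first (smallest) index on ties
    direction = m.vectors[idx] / mags[idx]
    return m.points[idx], direction, float(mags[idx])


def _barycentric_interpolate(
    mesh, vectors: np.ndarray, query: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Interpolate per-vertex vectors at query points on a sphere mesh.

    The containing triangle is found by central (gnomonic) projection: the
    ray from the sphere centre through the query point is intersected with
    candidate triangle planes (nearest centroids first) until the
    barycentric coordinates are all nonnegative.
    """
    from scipy.spatial import cKDTree

    v = mesh.vertices
    f = mesh.faces
    centroids = v[f].mean(axis=1)
    tree = cKDTree(centroids)
    k = min(24, len(f))
    _, cand = tree.query(query, k=k)
    cand = np.atleast_2d(cand)

    n = len(query)
    out = np.empty((n, vectors.shape[1]))
    done = np.zeros(n, dtype=bool)
    best_bary = np.full((n, 3), np.nan)
    best_tri = np.zeros(n, dtype=int)
    best_neg = np.full(n, -np.inf)  # most negative barycentric so far

    d = query - center
    for j in range(k):
        tri = cand[:, j]
        a, b, c = v[f[tri, 0]], v[f[tri, 1]], v[f[tri, 2]]
        # ray c0 + t*d intersects plane of (a,b,c); solve for barycentric of
        # the hit point directly: hit = a + s*(b-a) + r*(c-a)
        M = np.stack([b - a, c - a, -d], axis=2)  # (n,3,3) columns
        rhs = center - a
        ok = np.abs(np.linalg.det(M)) > 1e-30
        sol = np.full((n, 3), np.nan)
        sol[ok] = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
        s, r = sol[:, 0], sol[:, 1]
        w0 = 1.0 - s - r
        bary = np.stack([w0, s, r], axis=1)
        minb = np.nanmin(bary, axis=1)
        better = ~done & ok & (minb > best_neg)
        best_neg[better] = minb[better]
        best_bary[better] = bary[better]
        best_tri[better] = tri[better]
        inside = ~done & ok & (minb >= -1e-9)
        done |= inside
        if done.all():
            break
    # fall back to the best (least-negative) candidate, clipped
    bary = np.clip(best_bary, 0.0, None)
    bary /= bary.sum(axis=1, keepdims=True)
    vals = vectors[f[best_tri]]
    return np.einsum("nb,nbj->nj", bary, vals)


def geodesic_profile(
    m: EFieldMap,
    head: SphericalHeadModel,
    direction: str = "perpendicular",
    step: float = 1e-4,
    max_fraction: float = 0.999,
) -> FieldProfile:
    """Great-circle |E| profile through the field peak on the cortex sphere.

    ``direction`` selects the geodesic tangent at the peak: "parallel" runs
    along the peak-E direction projected on the sphere tangent plane,
    "perpendicular" at right angles to it.  Samples every ``step`` metres of
    arclength out to ``max_fraction`` of half the great circle on each side,
    interpolating the field barycentrically on the cortex mesh.
    """
    if direction not in ("parallel", "perpendicular"):
        raise ValueError("direction must be 'parallel' or 'perpendicular'")
    p, e_dir, _ = peak_field(m)
    c = head.center
    R = head.radius
    radial = (p - c) / np.linalg.norm(p - c)
    # tangential projection of the peak-E direction
    t_par = e_dir - (e_dir @ radial) * radial
    nrm = np.linalg.norm(t_par)
    if nrm < 1e-12:
        raise UndefinedPeakError("peak field is radial; tangent direction undefined")
    t_par /= nrm
    tangent = t_par if direction == "parallel" else np.cross(radial, t_par)

    s_max = max_fraction * np.pi * R
    n_side = int(np.floor(s_max / step))
    s = np.arange(-n_side, n_side + 1) * step
    ang = s / R
    pts = c + R * (np.cos(ang)[:, None] * radial + np.sin(ang)[:, None] * tangent)
    vec = _barycentric_interpolate(head.cortex_mesh, _map_on_mesh(m, head), pts, c)
    mags = np.linalg.norm(vec, axis=1)
    return FieldProfile(arclength=s, magnitudes=mags, direction=direction)


def _map_on_mesh(m: EFieldMap, head: SphericalHeadModel) -> np.ndarray:
    """Vertex-aligned field vectors; the map must be sampled on the cortex mesh."""
    if m.points.shape != head.cortex_mesh.vertices.shape or not np.allclose(
        m.points, head.cortex_mesh.vertices, atol=1e-9
    ):
        raise ValueError("field map is not sampled on the head's cortex mesh vertices")
    return m.vectors


def focality_width(p: FieldProfile, level_fraction: float = 1.0 / np.sqrt(2.0)) -> float:
    """Full width (m) at ``level_fraction`` of the profile maximum.

    The width spans the outermost crossings of the level on either side of
    the maximum, with linear interpolation between samples.
    """
    mags = p.magnitudes
    s = p.arclength
    imax = int(np.argmax(mags))
    level = mags[imax] * level_fraction

    def outermost_crossing(indices, side):
        """Last above-to-below crossing walking outward from the peak."""
        mo = mags[indices]
        if mo[-1] >= level:
            raise UnboundedWidthError(
                f"profile never drops below {level_fraction:.3f} of max on the {side} side"
            )
        k = int(np.flatnonzero(mo >= level)[-1])
        i0, i1 = indices[k], indices[k + 1]
        f = (level - mags[i0]) / (mags[i1] - mags[i0])
        return s[i0] + f * (s[i1] - s[i0])

    right = outermost_crossing(np.arange(imax, len(s)), "right")
    left = outermost_crossing(np.arange(imax, -1, -1), "left")
    return float(right - left)


def intensity_rising_phase(e_per_didt: float, pulse) -> float:
    """Mean |E| (V/m) over the rising phase of a pulse.

    ``e_per_didt`` is the field magnitude per unit current slew (V/m per
    A/s); the induced field follows dI/dt, so for a linear rise the result is
    exactly ``e_per_didt * peak_current / rise_time``.
    """
    t, didt = pulse.didt_segments()
    rise = pulse.phase_intervals()["rise"]
    t0, t1 = rise
    total = 0.0
    for (ta, tb), d in zip(zip(t[:-1], t[1:]), didt):
        a, b = max(ta, t0), min(tb, t1)
        if b > a:
            total += abs(d) * (b - a)
    return e_per_didt * total / (t1 - t0)
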