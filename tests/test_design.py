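import numpy as np
import pytest

from mtmskit import efield as ef
from mtmskit.design import (
    DesignSpec,
    Figure8Spec,
    StreamFunction,
    discretize_isolines,
    minimum_energy_stream,
    reference_field,
    svd_decompose,
)
from mtmskit.geometry import CoilPlane, SphericalHeadModel, make_plane_mesh
from oracles import kkt_equality_qp


@pytest.fixture(scope="module")
def small_problem(rat_head_small):
    """Coarse design problem: 642-vertex sphere, ~200-vertex plane."""
    head = rat_head_small
    mesh = make_plane_mesh(0.12, 0.09, 200)
    plane = CoilPlane(0.12, 0.09, 0.015, mesh)
    basis = ef.efield_basis(mesh, head, head.cortex_mesh.vertices)
    L = ef.inductance_matrix(mesh)
    target = reference_field(Figure8Spec(), head, head.cortex_mesh.vertices, 0.0)
    return head, plane, basis, L, target


class TestReferenceField:
    def test_90_degree_orientation_is_rotation(self, rat_head_small):
        head = rat_head_small
        pts = head.cortex_mesh.vertices
        m0 = reference_field(Figure8Spec(), head, pts, 0.0)
        m90 = reference_field(Figure8Spec(), head, pts, 90.0)
        # rotating evaluation points by -90 deg about the head axis and the
        # field vectors by +90 deg must reproduce the 0-deg map
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        local = pts - head.center
        pts_rot = local @ rot + head.center  # rotate by -90 (transpose)
        m0_at_rot = reference_field(Figure8Spec(), head, pts_rot, 0.0)
        np.testing.assert_allclose(
            m90.vectors, m0_at_rot.vectors @ rot.T, atol=1e-9 * np.abs(m0.vectors).max()
        )

    def test_peak_sits_under_wing_junction(self, rat_head_small):
        head = rat_head_small
        m = reference_field(Figure8Spec(), head, head.cortex_mesh.vertices, 0.0)
        p = m.points[np.argmax(m.magnitudes)]
        # junction is on the z-axis above the sphere top
        assert np.hypot(p[0], p[1]) < 0.004
        d = m.vectors[np.argmax(m.magnitudes)]
        assert d[0] / np.linalg.norm(d) > 0.99  # peak field along +x


class TestMinimumEnergyStream:
    def test_zero_target_returns_zero_stream(self, small_problem):
        head, plane, basis, L, target = small_problem
        zero = ef.EFieldMap(target.points, np.zeros_like(target.vectors))
        spec = DesignSpec(zero, 0.05, np.inf, plane)
        s = minimum_energy_stream(spec, basis, L)
        assert np.all(s.values == 0.0)

    def test_equality_only_matches_dense_kkt_oracle(self, small_problem):
        """With the tolerance band inactive (very loose) the solution is the
        peak-equality-constrained minimum-energy stream, solvable in closed
        form from the dense KKT system."""
        head, plane, basis, L, target = small_problem
        spec = DesignSpec(target, 0.9, np.inf, plane)
        s = minimum_energy_stream(spec, basis, L)
        peak = int(np.argmax(target.magnitudes))
        e_peak = target.magnitudes[peak]
        A = basis.matrix[3 * peak : 3 * peak + 3] / e_peak
        b = target.vectors[peak] / e_peak
        x = kkt_equality_qp(L.matrix, A, b)
        psi = s.values[basis.interior_idx]
        assert np.max(np.abs(psi - x)) / np.max(np.abs(x)) < 1e-8

    def test_solution_respects_field_band(self, small_problem):
        head, plane, basis, L, target = small_problem
        spec = DesignSpec(target, 0.05, np.inf, plane)
        s = minimum_energy_stream(spec, basis, L)
        e_peak = target.magnitudes.max()
        dev = basis.matrix @ s.values[basis.interior_idx] - target.vectors.reshape(-1)
        assert np.max(np.abs(dev)) <= 0.05 * e_peak * (1 + 1e-6)
        assert s.kkt_residual < 1e-6

    def test_energy_monotone_in_tolerance(self, small_problem):
        head, plane, basis, L, target = small_problem
        energies = []
        for tol in (0.10, 0.05, 0.02):
            s = minimum_energy_stream(DesignSpec(target, tol, np.inf, plane), basis, L)
            energies.append(s.energy)
        assert energies[0] <= energies[1] <= energies[2] * (1 + 1e-9)

    def test_density_bound_is_enforced(self, small_problem):
        head, plane, basis, L, target = small_problem
        loose = minimum_energy_stream(DesignSpec(target, 0.05, np.inf, plane), basis, L)
        D = ef._hat_current_basis(basis.mesh)
        # current magnitude per face of the unconstrained solution
        def max_density(s):
            cur = np.einsum(
                "fcx,fc->fx", D, s.values[basis.mesh.faces]
            )
            return np.linalg.norm(cur[:, :2], axis=1).max()

        bound = 0.5 * max_density(loose)
        tight = minimum_energy_stream(
            DesignSpec(target, 0.05, bound, plane), basis, L
        )
        # per-component bound: the vector norm may exceed it by sqrt(2)
        assert max_density(tight) <= bound * np.sqrt(2) * (1 + 1e-6)
        assert tight.energy >= loose.energy * (1 - 1e-9)


class TestSVD:
    def _stream(self, mesh, values):
        return StreamFunction(values, mesh)

    def test_orthogonal_inputs_pass_through(self):
        mesh = make_plane_mesh(0.1, 0.1, 100)
        n = mesh.n_vertices
        a = np.zeros(n); a[10] = 1.0
        b = np.zeros(n); b[20] = 1.0
        out = svd_decompose([self._stream(mesh, a), self._stream(mesh, b)])
        for o in out:
            matches = [
                min(np.linalg.norm(o.values - s), np.linalg.norm(o.values + s))
                for s in (a, b)
            ]
            assert min(matches) < 1e-12

    def test_outputs_mutually_orthogonal(self):
        mesh = make_plane_mesh(0.1, 0.1, 100)
        rng = np.random.default_rng(0)
        x = rng.normal(size=mesh.n_vertices)
        y = 0.8 * x + 0.3 * rng.normal(size=mesh.n_vertices)
        out = svd_decompose([self._stream(mesh, x), self._stream(mesh, y)])
        assert abs(out[0].values @ out[1].values) < 1e-10 * (
            np.linalg.norm(out[0].values) * np.linalg.norm(out[1].values) + 1e-30
        )

    def test_span_is_preserved(self):
        mesh = make_plane_mesh(0.1, 0.1, 100)
        rng = np.random.default_rng(1)
        x = rng.normal(size=mesh.n_vertices)
        y = rng.normal(size=mesh.n_vertices)
        out = svd_decompose([self._stream(mesh, x), self._stream(mesh, y)])
        U = np.column_stack([o.values / np.linalg.norm(o.values) for o in out])
        for v in (x, y):
            recon = U @ (U.T @ v)
            assert np.linalg.norm(recon - v) < 1e-10 * np.linalg.norm(v)

    def test_mismatched_meshes_rejected(self):
        m1 = make_plane_mesh(0.1, 0.1, 100)
        m2 = make_plane_mesh(0.1, 0.1, 150)
        with pytest.raises(ValueError):
            svd_decompose(
                [
                    self._stream(m1, np.zeros(m1.n_vertices)),
                    self._stream(m2, np.zeros(m2.n_vertices)),
                ]
            )


class TestIsolines:
    def _gaussian_bump(self, n=400):
        mesh = make_plane_mesh(0.1, 0.1, n)
        v = mesh.vertices
        psi = np.exp(-(v[:, 0] ** 2 + v[:, 1] ** 2) / (2 * 0.02**2))
        psi[mesh.boundary_mask] = 0.0
        return StreamFunction(psi, mesh)

    def test_gaussian_bump_gives_nested_concentric_loops(self):
        w = discretize_isolines(self._gaussian_bump(), 4)
        assert w.n_loops == 4
        assert all(p == 1 for p in w.polarities)
        radii = sorted(np.linalg.norm(l[:-1, :2], axis=1).mean() for l in w.loops)
        assert all(a < b for a, b in zip(radii, radii[1:]))

    def test_two_lobed_antisymmetric_stream_gives_seven_per_wing(self):
        mesh = make_plane_mesh(0.16, 0.08, 800)
        v = mesh.vertices
        lobe = lambda x0: np.exp(
            -(((v[:, 0] - x0) ** 2) + v[:, 1] ** 2) / (2 * 0.018**2)
        )
        psi = lobe(-0.035) - lobe(0.035)
        psi[mesh.boundary_mask] = 0.0
        w = discretize_isolines(StreamFunction(psi, mesh), 14)
        assert w.n_loops == 14
        assert sum(1 for p in w.polarities if p > 0) == 7
        assert sum(1 for p in w.polarities if p < 0) == 7

    def test_current_per_turn_is_bin_width(self):
        s = self._gaussian_bump()
        w = discretize_isolines(s, 4)
        assert w.current_per_turn == pytest.approx(np.ptp(s.values) / 4)

    def test_layers_alternate_with_wire_offset(self):
        w = discretize_isolines(self._gaussian_bump(), 4, wire_diameter=1.7e-3)
        z = [l[0, 2] for l in w.loops]
        assert set(w.layers) == {0, 1}
        # layers straddle the nominal plane, one wire diameter apart
        for zi, lay in zip(z, w.layers):
            assert zi == pytest.approx((lay - 0.5) * 1.7e-3, abs=1e-12)
        z0 = [zi for zi, lay in zip(z, w.layers) if lay == 0]
        z1 = [zi for zi, lay in zip(z, w.layers) if lay == 1]
        assert z1[0] - z0[0] == pytest.approx(1.7e-3, abs=1e-12)

    def test_discretized_field_tracks_stream_field(self, rat_head_small):
        """Windings contoured from a stream reproduce its continuous field."""
        head = rat_head_small
        s = self._gaussian_bump(800)
        basis = ef.efield_basis(s.mesh, head, head.cortex_mesh.vertices)
        m_cont = basis.field_of(s.values[basis.interior_idx])
        w = discretize_isolines(s, 14)
        m_disc = ef.efield_segments(w, head, head.cortex_mesh.vertices)
        dev = np.linalg.norm(
            m_disc.vectors * w.current_per_turn - m_cont.vectors, axis=1
        ).max() / np.linalg.norm(m_cont.vectors, axis=1).max()
        assert dev < 0.05

    def test_non_boundary_zero_stream_raises(self):
        mesh = make_plane_mesh(0.1, 0.1, 200)
        psi = mesh.vertices[:, 0].copy()  # linear ramp, nonzero on boundary
        with pytest.raises(Exception, match="boundary"):
            discretize_isolines(StreamFunction(psi, mesh), 3)
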