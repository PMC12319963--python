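import numpy as np
import pytest

from mtmskit import efield as ef
from mtmskit.geometry import SphericalHeadModel, WindingPath, make_plane_mesh
from oracles import bem_efield_segments, neumann_polyline_inductance, vector_potential_per_current


def interior_points(head, n=30, rmax=0.85, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    r = rmax * head.radius * rng.uniform(0.2, 1.0, (n, 1))
    return head.center + d * r


class TestSphericalConductorField:
    def test_coaxial_loop_field_is_azimuthal_and_matches_vector_potential(
        self, rat_head_small, single_loop_winding
    ):
        """For a loop coaxial with the sphere axis the secondary charge term
        vanishes, so E must equal -dA/dt and be purely azimuthal."""
        head = rat_head_small
        pts = interior_points(head)
        E = ef.efield_segments(single_loop_winding, head, pts, refine=3).vectors
        starts, ends, cur = single_loop_winding.segments()
        Edir = -vector_potential_per_current(starts, ends, np.sign(cur), pts)
        assert np.linalg.norm(E - Edir) / np.linalg.norm(Edir) < 2e-3
        # azimuthal: no radial (about sphere center) and no z component
        radial = (pts - head.center) / np.linalg.norm(pts - head.center, axis=1)[:, None]
        rad = np.abs(np.einsum("ij,ij->i", E, radial))
        assert rad.max() < 1e-9 * np.linalg.norm(E, axis=1).max()
        assert np.abs(E[:, 2]).max() < 1e-9 * np.linalg.norm(E, axis=1).max()

    def test_radial_component_vanishes_for_any_winding(self, rat_head_small, circular_loop):
        head = rat_head_small
        loops = [circular_loop(0.012, (0.01, 0.005, 0.002), tilt=0.3)]
        w = WindingPath(loops, [1], [0], wire_diameter=1e-3)
        pts = interior_points(head, seed=1)
        E = ef.efield_segments(w, head, pts).vectors
        radial = (pts - head.center) / np.linalg.norm(pts - head.center, axis=1)[:, None]
        rad = np.abs(np.einsum("ij,ij->i", E, radial))
        assert rad.max() < 1e-6 * np.linalg.norm(E, axis=1).max()

    def test_didt_linearity_and_loop_superposition(self, rat_head_small, circular_loop):
        head = rat_head_small
        l1 = circular_loop(0.015, (0.005, 0, 0))
        l2 = circular_loop(0.01, (-0.01, 0.004, 0.003), tilt=-0.2)
        pts = interior_points(head, n=10, seed=2)
        w12 = WindingPath([l1, l2], [1, -1], [0, 0], wire_diameter=1e-3)
        w1 = WindingPath([l1], [1], [0], wire_diameter=1e-3)
        w2 = WindingPath([l2], [-1], [0], wire_diameter=1e-3)
        E12 = ef.efield_segments(w12, head, pts).vectors
        E1 = ef.efield_segments(w1, head, pts).vectors
        E2 = ef.efield_segments(w2, head, pts).vectors
        scale = np.abs(E12).max()
        np.testing.assert_allclose(E12, E1 + E2, rtol=0.0, atol=1e-10 * scale)
        # doubling dI/dt doubles E exactly
        m = ef.efield_segments(w12, head, pts)
        np.testing.assert_array_equal(m.scaled(2.0).vectors, 2.0 * m.vectors)

    def test_against_surface_charge_bem(self, rat_head_small, circular_loop):
        """Closed-form solution vs an independent BEM solve; the coarse test
        sphere allows 2.5% (the full-resolution check lives in acceptance)."""
        head = rat_head_small
        loops = [
            circular_loop(0.014, (0.008, 0.003, 0.001), tilt=0.25),
            circular_loop(0.009, (-0.012, -0.006, 0.004), tilt=-0.1),
        ]
        w = WindingPath(loops, [1, -1], [0, 0], wire_diameter=1e-3)
        pts = interior_points(head, n=25, seed=3)
        E = ef.efield_segments(w, head, pts, refine=3).vectors
        Eb = bem_efield_segments(w, head, pts)
        dev = np.linalg.norm(E - Eb, axis=1).max() / np.linalg.norm(Eb, axis=1).max()
        assert dev < 0.025

    def test_winding_inside_sphere_rejected(self, rat_head_small, circular_loop):
        loop = circular_loop(0.005, tuple(rat_head_small.center))
        w = WindingPath([loop], [1], [0], wire_diameter=1e-3)
        with pytest.raises(ef.InvalidGeometryError):
            ef.efield_segments(w, rat_head_small, rat_head_small.cortex_mesh.vertices)

    def test_points_outside_sphere_rejected(self, rat_head_small, single_loop_winding):
        with pytest.raises(ef.InvalidGeometryError):
            ef.efield_segments(
                single_loop_winding, rat_head_small, np.array([[0.0, 0.0, 0.1]])
            )


class TestFieldBasis:
    @pytest.fixture(scope="class")
    def setup(self, rat_head_small):
        mesh = make_plane_mesh(0.08, 0.08, 120)
        basis = ef.efield_basis(mesh, rat_head_small, rat_head_small.cortex_mesh.vertices)
        return mesh, basis

    def test_zero_stream_zero_field(self, setup, rat_head_small):
        _, basis = setup
        m = basis.field_of(np.zeros(len(basis.interior_idx)))
        assert np.all(m.vectors == 0.0)

    def test_linearity_matches_column_sum(self, setup):
        _, basis = setup
        rng = np.random.default_rng(0)
        psi = rng.normal(size=len(basis.interior_idx))
        direct = (basis.matrix * psi[None, :]).sum(axis=1)
        np.testing.assert_allclose(basis.matrix @ psi, direct, rtol=1e-12)

    def test_constant_stream_matches_boundary_loop(self, rat_head_small):
        """psi = 1 on all interior vertices is equivalent to a single loop
        half a cell inside the rectangle boundary."""
        head = rat_head_small
        mesh = make_plane_mesh(0.08, 0.08, 400)
        basis = ef.efield_basis(mesh, head, head.cortex_mesh.vertices)
        psi = np.ones(len(basis.interior_idx))
        E_stream = basis.field_of(psi).vectors

        xs = np.unique(mesh.vertices[:, 0])
        dx = xs[1] - xs[0]
        ys = np.unique(mesh.vertices[:, 1])
        dy = ys[1] - ys[0]
        hx, hy = 0.04 - dx / 2, 0.04 - dy / 2
        rect = np.array(
            [[-hx, -hy, 0], [hx, -hy, 0], [hx, hy, 0], [-hx, hy, 0], [-hx, -hy, 0]]
        )
        # resample edges for quadrature fidelity
        dense = []
        for a, b in zip(rect[:-1], rect[1:]):
            for t in np.linspace(0, 1, 40, endpoint=False):
                dense.append(a + t * (b - a))
        dense.append(rect[0])
        w = WindingPath([np.array(dense)], [1], [0], wire_diameter=1e-3)
        E_loop = ef.efield_segments(w, head, head.cortex_mesh.vertices, refine=3).vectors
        dev = np.linalg.norm(E_stream - E_loop, axis=1).max() / np.linalg.norm(
            E_loop, axis=1
        ).max()
        assert dev < 0.02

    def test_plane_touching_sphere_rejected(self, rat_head_small):
        mesh = make_plane_mesh(0.08, 0.08, 120)
        shifted = type(mesh)(
            mesh.vertices + np.array([0, 0, rat_head_small.center[2]]),
            mesh.faces,
            boundary_mask=mesh.boundary_mask,
        )
        with pytest.raises(ef.InvalidGeometryError):
            ef.efield_basis(shifted, rat_head_small, rat_head_small.cortex_mesh.vertices)


class TestInductance:
    def test_matrix_symmetric_positive_definite(self):
        mesh = make_plane_mesh(0.08, 0.08, 150)
        L = ef.inductance_matrix(mesh)
        M = L.matrix
        assert np.max(np.abs(M - M.T)) <= 1e-10 * np.max(np.abs(M))
        assert np.linalg.eigvalsh(M).min() > 0

    def test_random_streams_have_positive_energy(self):
        mesh = make_plane_mesh(0.06, 0.06, 100)
        L = ef.inductance_matrix(mesh)
        rng = np.random.default_rng(0)
        for _ in range(100):
            psi = rng.normal(size=L.matrix.shape[0])
            assert psi @ L.matrix @ psi > 0

    def test_circular_loop_inductance_closed_form(self, circular_loop):
        a0, rw = 0.010, 0.85e-3
        w = WindingPath([circular_loop(a0, n=129)], [1], [0], wire_diameter=2 * rw)
        L = ef.winding_inductance(w)
        Lref = ef.MU0 * a0 * (np.log(8 * a0 / rw) - 2.0)
        assert abs(L - Lref) / Lref < 0.02

    def test_far_coaxial_loops_add(self, circular_loop):
        a0 = 0.01
        l1 = circular_loop(a0, (0, 0, 0))
        l2 = circular_loop(a0, (0, 0, 1.0))  # 1 m apart: negligible mutual
        w1 = WindingPath([l1], [1], [0], wire_diameter=1e-3)
        w2 = WindingPath([l1, l2], [1, 1], [0, 0], wire_diameter=1e-3)
        assert abs(ef.winding_inductance(w2) - 2 * ef.winding_inductance(w1)) < 0.01 * ef.winding_inductance(w1)

    def test_two_loop_winding_matches_neumann_oracle(self, circular_loop):
        loops = [circular_loop(0.012, n=65), circular_loop(0.012, (0, 0, 0.0017), n=65)]
        w = WindingPath(loops, [1, 1], [0, 1], wire_diameter=1.7e-3)
        L = ef.winding_inductance(w)
        Lo = neumann_polyline_inductance(loops, [1, 1], 0.85e-3, n_sub=16)
        assert abs(L - Lo) / Lo < 0.03

    def test_resistance_scales_with_length_over_area(self, circular_loop):
        w = WindingPath([circular_loop(0.01, n=257)], [1], [0], wire_diameter=1.7e-3)
        R = ef.winding_resistance(w)
        expected = 1.68e-8 * w.total_length() / (np.pi * 0.85e-3**2)
        assert R == pytest.approx(expected, rel=1e-12)

    def test_zero_wire_diameter_rejected(self, circular_loop):
        with pytest.raises(ValueError):
            WindingPath([circular_loop()], [1], [0], wire_diameter=0.0)


class TestEFieldMapIO:
    def test_csv_round_trip(self, tmp_path, rat_head_small, single_loop_winding):
        m = ef.efield_segments(
            single_loop_winding, rat_head_small, rat_head_small.cortex_mesh.vertices[:20]
        )
        path = tmp_path / "map.csv"
        m.to_csv(path)
        r = ef.EFieldMap.from_csv(path)
        np.testing.assert_allclose(r.points, m.points, rtol=1e-12)
        np.testing.assert_allclose(r.vectors, m.vectors, rtol=1e-12)
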