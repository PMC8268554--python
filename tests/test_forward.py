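"""Forward solver: patterns, FEM assembly, reciprocity, Jacobian, noise."""

import numpy as np
import pytest

from eitherm.forward import (ForwardOperator, add_measurement_noise,
                             assemble_conductance, build_pattern,
                             compute_jacobian, solve_forward,
                             transfer_impedance_matrix)
from eitherm.mesh import ConductivityField, TetMesh
from eitherm.phantom import ball_mesh


class TestPattern:
    def test_16_electrode_offset7_yields_192(self):
        pat = build_pattern(16, 7)
        assert len(pat.injections) == 16
        assert pat.n_measurements == 192

    def test_8_electrode_offset3_yields_32(self):
        # 8 adjacent pairs, 4 touch the two (non-adjacent) injection
        # electrodes, leaving 4 pairs per injection
        pat = build_pattern(8, 3)
        assert pat.n_measurements == 32

    def test_no_measurement_shares_injection_electrode(self):
        pat = build_pattern(16, 7)
        for _, inj, pair in pat.flat():
            assert not (set(inj) & set(pair))

    @pytest.mark.parametrize("offset", [1, 15])
    def test_adjacent_offsets_rejected(self, offset):
        with pytest.raises(ValueError):
            build_pattern(16, offset)


def _single_tet_mesh():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    return TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([0]))


class TestAssembly:
    def test_single_tet_matches_hand_assembly(self):
        # reference tet: V = 1/6, grad phi_0 = (-1,-1,-1), grad phi_i = e_i
        mesh = _single_tet_mesh()
        sigma = ConductivityField(np.array([2.0]))
        _, A, _ = assemble_conductance(mesh, sigma)
        G = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        expected = 2.0 * (1 / 6) * G @ G.T
        assert np.allclose(A.toarray(), expected)

    def test_symmetry_and_zero_row_sums(self, small_setup):
        _, _, mesh, sigma = small_setup
        _, A, _ = assemble_conductance(mesh, sigma)
        diff = (A - A.T).tocoo()
        assert np.max(np.abs(diff.data)) if diff.nnz else 0 == 0
        rowsum = np.asarray(A.sum(axis=1)).ravel()
        assert np.max(np.abs(rowsum)) < 1e-10 * np.max(A.diagonal())


class TestSolveForward:
    def test_voltages_halve_when_sigma_doubles(self, small_setup, pattern16):
        _, _, mesh, sigma = small_setup
        v1 = solve_forward(mesh, sigma, pattern16)
        v2 = solve_forward(mesh, ConductivityField(2 * sigma.values), pattern16)
        assert np.allclose(2 * v2.values, v1.values, rtol=1e-10)

    def test_reciprocity(self, small_setup):
        _, _, mesh, sigma = small_setup
        op = ForwardOperator(mesh, sigma)
        n = mesh.electrode_nodes
        u_ab = op.electrode_field(2, 9, 1.0)
        u_cd = op.electrode_field(4, 5, 1.0)
        z1 = u_ab[n[4]] - u_ab[n[5]]
        z2 = u_cd[n[2]] - u_cd[n[9]]
        assert z1 == pytest.approx(z2, rel=1e-8)

    def test_ground_choice_immaterial(self, small_setup, pattern16):
        _, _, mesh, sigma = small_setup
        v1 = ForwardOperator(mesh, sigma).voltages(pattern16)
        interior = np.setdiff1d(np.arange(mesh.n_nodes), mesh.boundary_nodes())
        v2 = ForwardOperator(mesh, sigma, ground_node=int(interior[5])).voltages(pattern16)
        assert np.allclose(v1.values, v2.values, rtol=1e-8, atol=1e-14)


def _sphere_surface_potential(theta, sigma, a):
    """Closed-form surface potential of a unit point current source on a
    grounded-mean conducting sphere: series sum((2n+1)/n) P_n(cos t)."""
    s = np.sin(theta / 2.0)
    return (1.0 / (4 * np.pi * sigma * a)) * (1.0 / s - 2.0 + np.log(1.0 / (s * (1 + s))))


class TestSphereOracle:
    def test_four_electrode_impedance_matches_closed_form(self):
        # independent oracle: Legendre generating functions give the surface
        # potential in closed form; compare a four-electrode transfer
        # impedance far from the injection singularities
        a, sigma = 0.1, 0.5
        mesh = ball_mesh(a, n=9)
        surf = mesh.boundary_nodes()
        pts = mesh.node_coords
        def node_at(direction):
            d = np.asarray(direction, float); d /= np.linalg.norm(d)
            return surf[np.argmax(pts[surf] @ d / np.linalg.norm(pts[surf], axis=1))]
        # injection near-antipodal, measurement on a perpendicular arc
        n_inj = [node_at((0, 0, 1)), node_at((0.05, 0, -1))]
        n_meas = [node_at((1, 0, 0.3)), node_at((1, 0, -0.35))]
        mesh.electrode_nodes = [int(x) for x in (n_inj + n_meas)]
        op = ForwardOperator(mesh, ConductivityField(np.full(mesh.n_elements, sigma)))
        u = op.electrode_field(0, 1, 1.0)
        z_fem = u[mesh.electrode_nodes[2]] - u[mesh.electrode_nodes[3]]

        def analytic(src_node, meas_node, sign):
            ps, pm = pts[src_node], pts[meas_node]
            ct = np.clip(ps @ pm / (np.linalg.norm(ps) * np.linalg.norm(pm)), -1, 1)
            return sign * _sphere_surface_potential(np.arccos(ct), sigma, a)

        z_true = sum(analytic(s, m, sgn_s * sgn_m)
                     for s, sgn_s in zip(n_inj, (1, -1))
                     for m, sgn_m in zip(n_meas, (1, -1)))
        assert z_fem == pytest.approx(z_true, rel=0.05)

    def test_refinement_convergence(self):
        # successive refinement changes the four-electrode impedance < 2 %
        a, sigma = 0.1, 0.5
        vals = []
        for n in (6, 9):
            mesh = ball_mesh(a, n=n)
            surf = mesh.boundary_nodes()
            pts = mesh.node_coords

            def node_at(direction):
                d = np.asarray(direction, float); d /= np.linalg.norm(d)
                return int(surf[np.argmax(pts[surf] @ d / np.linalg.norm(pts[surf], axis=1))])

            mesh.electrode_nodes = [node_at((0, 0, 1)), node_at((0.05, 0, -1)),
                                    node_at((1, 0, 0.3)), node_at((1, 0, -0.35))]
            op = ForwardOperator(mesh, ConductivityField(np.full(mesh.n_elements, sigma)))
            u = op.electrode_field(0, 1, 1.0)
            vals.append(u[mesh.electrode_nodes[2]] - u[mesh.electrode_nodes[3]])
        assert abs(vals[1] - vals[0]) / abs(vals[1]) < 0.02


class TestJacobian:
    def test_matches_central_finite_differences(self, small_setup, pattern16, rng):
        _, _, mesh, sigma = small_setup
        J = compute_jacobian(mesh, sigma, pattern16)
        scale = np.max(np.abs(J.entries))
        for e in rng.choice(mesh.n_elements, 4, replace=False):
            d = 1e-6 * sigma.values[e]
            up = sigma.values.copy(); up[e] += d
            dn = sigma.values.copy(); dn[e] -= d
            fd = (solve_forward(mesh, ConductivityField(up), pattern16).values
                  - solve_forward(mesh, ConductivityField(dn), pattern16).values) / (2 * d)
            assert np.max(np.abs(fd - J.entries[:, e])) < 1e-4 * np.max(np.abs(J.entries[:, e]))

    def test_scales_inverse_square_with_sigma(self, small_setup, pattern16):
        _, _, mesh, sigma = small_setup
        J1 = compute_jacobian(mesh, sigma, pattern16)
        c = 3.0
        J2 = compute_jacobian(mesh, ConductivityField(c * sigma.values), pattern16)
        assert np.allclose(J2.entries, J1.entries / c ** 2, rtol=1e-8,
                           atol=1e-10 * np.max(np.abs(J1.entries)))

    def test_linear_map_on_zero_perturbation(self, small_setup, pattern16):
        _, _, mesh, sigma = small_setup
        J = compute_jacobian(mesh, sigma, pattern16)
        assert np.all(J.entries @ np.zeros(mesh.n_elements) == 0)


class TestTransferImpedance:
    def test_symmetric_zero_diagonal(self, small_setup):
        _, _, mesh, sigma = small_setup
        Z = transfer_impedance_matrix(mesh, sigma)
        assert np.allclose(Z, Z.T, rtol=1e-10)
        assert np.all(np.diag(Z) == 0)

    def test_global_scaling(self, small_setup):
        _, _, mesh, sigma = small_setup
        Z1 = transfer_impedance_matrix(mesh, sigma)
        Z2 = transfer_impedance_matrix(mesh, ConductivityField(1.4 * sigma.values))
        # uniform 40 % conductivity increase reduces every impedance by 1/1.4
        assert np.allclose(Z2, Z1 / 1.4, rtol=1e-10)


class TestNoise:
    def test_infinite_snr_is_identity(self, small_setup, pattern16):
        _, _, mesh, sigma = small_setup
        vref = solve_forward(mesh, sigma, pattern16)
        v = solve_forward(mesh, ConductivityField(sigma.values * 1.1), pattern16)
        out = add_measurement_noise(v, vref, np.inf, seed=0)
        assert np.array_equal(out.values, v.values)

    def test_zero_change_rejected(self, small_setup, pattern16):
        _, _, mesh, sigma = small_setup
        v = solve_forward(mesh, sigma, pattern16)
        with pytest.raises(ValueError):
            add_measurement_noise(v, v, 20.0, seed=0)

    def test_noise_statistics(self, pattern16, rng):
        # sample std over many draws matches rms(dv)/10^(snr/20) to < 0.5 %
        from eitherm.forward import MeasurementFrame

        vref = MeasurementFrame(rng.normal(0, 1e-3, 192), pattern16)
        v = MeasurementFrame(vref.values + rng.normal(0, 1e-4, 192), pattern16)
        dv_rms = np.sqrt(np.mean((v.values - vref.values) ** 2))
        draws = np.stack([
            add_measurement_noise(v, vref, 20.0, seed=s).values - v.values
            for s in range(600)
        ])
        assert draws.std() == pytest.approx(dv_rms / 10.0, rel=0.005)
        # determinism under a fixed seed
        a = add_measurement_noise(v, vref, 20.0, seed=7).values
        b = add_measurement_noise(v, vref, 20.0, seed=7).values
        assert np.array_equal(a, b)
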