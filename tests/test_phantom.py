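"""Phantom geometry: mesh validity, electrodes, heating scenarios."""

import numpy as np
import pytest

from eitherm.mesh import ConductivityField
from eitherm.phantom import (HeatingScenario, PhantomSpec, apply_gaussian_heating,
                             build_phantom, gaussian_multiplier,
                             insert_spherical_anomaly, place_electrodes,
                             scenario_fixture, SCENARIO_IDS)
from eitherm.tissues import default_tissue_table


class TestBuildPhantom:
    def test_mesh_validity_and_all_tissues_present(self, small_setup):
        spec, table, mesh, sigma = small_setup
        assert np.all(mesh.volumes > 0)
        present = {table.name_of(int(t)) for t in np.unique(mesh.labels)}
        expected = {"skin", "fat", "muscle", "bone", "organ", "urine", "tumor"}
        assert expected <= present
        assert len(sigma.values) == mesh.n_elements

    def test_volume_matches_elliptic_cylinder(self, small_setup):
        spec, _, mesh, _ = small_setup
        assert mesh.volumes.sum() == pytest.approx(spec.analytic_volume(), rel=0.02)

    def test_element_count_near_target(self, small_setup):
        spec, *_ = small_setup
        mesh = small_setup[2]
        assert abs(mesh.n_elements - spec.target_elements) <= 0.3 * spec.target_elements

    def test_homogeneous_without_inclusions(self, table):
        spec = PhantomSpec(target_elements=4000, skin_frac=0.0, fat_frac=0.0,
                           inclusions=())
        mesh, sigma = build_phantom(spec, table)
        assert len(np.unique(mesh.labels)) == 1
        assert np.allclose(sigma.values, sigma.values[0])

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(a=-0.1)

    def test_inclusion_outside_boundary_rejected(self):
        from eitherm.phantom import Inclusion

        with pytest.raises(ValueError):
            PhantomSpec(inclusions=(Inclusion("tumor", "sphere", (0.2, 0.0, 0.0), (0.01,)),))

    def test_deterministic_rebuild(self, small_spec, table):
        m1, s1 = build_phantom(small_spec, table)
        m2, s2 = build_phantom(small_spec, table)
        assert np.array_equal(m1.node_coords, m2.node_coords)
        assert np.array_equal(m1.tets, m2.tets)
        assert np.array_equal(s1.values, s2.values)


class TestElectrodes:
    def test_two_ring_interleaved_geometry(self, small_setup):
        spec, _, mesh, _ = small_setup
        nodes = mesh.node_coords[mesh.electrode_nodes]
        assert len(nodes) == 16
        z = np.round(nodes[:, 2], 6)
        heights = np.unique(z)
        assert len(heights) == 2
        # consecutive electrodes alternate rings
        ring = (z == heights.max()).astype(int)
        assert np.all(ring[::2] == ring[0]) and np.all(ring[1::2] == 1 - ring[0])
        # per-ring angular spacing 45 deg, half-spacing offset between rings
        ang = np.degrees(np.arctan2(nodes[:, 1] / spec.b, nodes[:, 0] / spec.a)) % 360
        for r in (0, 1):
            d = np.sort(ang[r::2])
            assert np.allclose(np.diff(d), 45.0, atol=1.0)
        offset = (ang[1] - ang[0]) % 45
        assert offset == pytest.approx(22.5, abs=1.0)

    def test_single_ring(self, small_spec, table):
        mesh, _ = build_phantom(small_spec, table)
        nodes = place_electrodes(mesh, 8, 1)
        ang = np.sort(np.degrees(np.arctan2(
            mesh.node_coords[nodes, 1] / small_spec.b,
            mesh.node_coords[nodes, 0] / small_spec.a)) % 360)
        assert np.allclose(np.diff(ang), 45.0, atol=1.0)

    def test_indivisible_count_rejected(self, small_setup):
        mesh = small_setup[2]
        with pytest.raises(ValueError):
            place_electrodes(mesh, 15, 2)


class TestGaussianHeating:
    def test_multiplier_values(self):
        # peak increase at the centre, 1 + 0.4 e^{-1/2} at r = R
        assert gaussian_multiplier(0.0, 0.03, 0.4) == pytest.approx(1.4)
        assert gaussian_multiplier(0.03, 0.03, 0.4) == pytest.approx(
            1 + 0.4 * np.exp(-0.5), rel=1e-12)

    def test_zero_peak_is_identity(self, small_setup):
        _, _, mesh, sigma = small_setup
        sc = HeatingScenario((0, 0, 0), radius_mm=30.0, peak=0.0)
        out = apply_gaussian_heating(sigma, sc, mesh)
        assert np.array_equal(out.values, sigma.values)

    def test_multiplier_monotone_and_bounded(self, small_setup):
        _, _, mesh, sigma = small_setup
        sc = HeatingScenario((-79.0, 18.0, 15.0), radius_mm=30.0, peak=0.4)
        out = apply_gaussian_heating(sigma, sc, mesh)
        mult = out.values / sigma.values
        assert np.all(mult >= 1.0) and np.all(mult <= 1.4 + 1e-12)
        r = np.linalg.norm(mesh.centroids - sc.center, axis=1)
        order = np.argsort(r)
        assert np.all(np.diff(mult[order]) <= 1e-12)

    def test_cutoff_confines_change(self, small_setup):
        _, _, mesh, sigma = small_setup
        sc = HeatingScenario((-79.0, 18.0, 15.0), radius_mm=30.0, peak=0.4,
                             cutoff_mm=30.0)
        out = apply_gaussian_heating(sigma, sc, mesh)
        r = np.linalg.norm(mesh.centroids - sc.center, axis=1)
        assert np.array_equal(out.values[r > 0.03], sigma.values[r > 0.03])
        assert np.any(out.values[r <= 0.03] > sigma.values[r <= 0.03])


class TestAnomaly:
    def test_inside_set_outside_unchanged(self, small_setup):
        _, _, mesh, sigma = small_setup
        out = insert_spherical_anomaly(sigma, mesh, (44.0, 27.0, 15.0), 50.0, 0.0)
        r = np.linalg.norm(mesh.centroids - np.array([0.044, 0.027, 0.015]), axis=1)
        inside = r <= 0.025
        assert inside.any()
        assert np.all(out.values[inside] == 0.0)
        assert np.array_equal(out.values[~inside], sigma.values[~inside])

    def test_zero_diameter_noop(self, small_setup):
        _, _, mesh, sigma = small_setup
        out = insert_spherical_anomaly(sigma, mesh, (0, 0, 0), 0.0, 1.0)
        assert np.array_equal(out.values, sigma.values)

    def test_sphere_outside_mesh_warns(self, small_setup):
        _, _, mesh, sigma = small_setup
        with pytest.warns(UserWarning):
            out = insert_spherical_anomaly(sigma, mesh, (500.0, 0, 0), 5.0, 0.0)
        assert np.array_equal(out.values, sigma.values)


class TestScenarioFixtures:
    def test_diameters(self):
        diam = {"P1": 60, "P2": 40, "P3": 80, "P4": 60, "P5": 60, "air": 50}
        for sid, d in diam.items():
            sc = scenario_fixture(sid)
            assert 2 * sc.radius_mm == pytest.approx(d)

    def test_p1_p2_p3_share_center(self):
        c1 = scenario_fixture("P1").center_mm
        assert scenario_fixture("P2").center_mm == c1
        assert scenario_fixture("P3").center_mm == c1

    def test_air_scenario_zero_sigma(self):
        sc = scenario_fixture("air")
        assert sc.anomaly["sigma_value"] == 0.0
        assert sc.peak == 0.0

    def test_centers_inside_phantom(self):
        spec = PhantomSpec()
        for sid in SCENARIO_IDS:
            sc = scenario_fixture(sid, spec)
            assert spec.inside(sc.center[None, :])[0]

    def test_unknown_id(self):
        with pytest.raises(KeyError):
            scenario_fixture("P9")
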