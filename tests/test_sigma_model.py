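"""Conductivity-change model, its inverse, and two-frequency separation."""

import numpy as np
import pytest

from eitherm.bioheat import PerfusionCurve, optimistic_perfusion, pessimistic_perfusion
from eitherm.mesh import ConductivityField
from eitherm.multifreq import SeparationInputs, separate_perfusion, separate_temperature
from eitherm.sigma_model import (ConductivityChangeModel, conductivity_change,
                                 fields_to_sigma, temperature_from_conductivity,
                                 temperature_map_from_sigma)
from eitherm.tissues import default_tissue_table


class TestConductivityChange:
    def test_baseline_zero(self):
        m = ConductivityChangeModel(tc=0.02, alpha=0.08)
        assert conductivity_change(0.0, 1.0, m) == 0.0

    def test_pure_perfusion_value(self):
        # dT = 0, omega = 2: 0.08 (sqrt 2 - 1) ~ 3.31 %
        m = ConductivityChangeModel(tc=0.02, alpha=0.08)
        assert conductivity_change(0.0, 2.0, m) == pytest.approx(
            0.08 * (np.sqrt(2) - 1), rel=1e-12)

    def test_combined_value(self):
        # dT = 4, omega = 4: 0.08 + 0.08 * 1 * 1.08 = 0.1664
        m = ConductivityChangeModel(tc=0.02, alpha=0.08)
        assert conductivity_change(4.0, 4.0, m) == pytest.approx(0.1664, rel=1e-12)

    def test_monotone_in_temperature_all_tissue_variants(self):
        table = default_tissue_table()
        T = np.linspace(0.0, 10.0, 400)
        for model in (optimistic_perfusion(), pessimistic_perfusion()):
            for tissue in ("muscle", "fat", "tumor"):
                curve = model.curves[tissue]
                for alpha in (0.24, 0.08):
                    m = ConductivityChangeModel(tc=0.02, alpha=alpha)
                    ds = conductivity_change(T, curve(37.0 + T), m)
                    assert np.all(np.diff(ds) > 0)

    def test_lf_change_dominates_hf(self):
        # alpha_LF > alpha_HF makes the perfusion contribution larger at LF
        mlf = ConductivityChangeModel(tc=0.02, alpha=0.24)
        mhf = ConductivityChangeModel(tc=0.02, alpha=0.08)
        T = np.linspace(0, 8, 50)
        omega = 1.0 + 0.5 * T
        assert np.all(conductivity_change(T, omega, mlf)
                      >= conductivity_change(T, omega, mhf))


class TestTemperatureInversion:
    def test_zero_change_zero_rise(self):
        m = ConductivityChangeModel(tc=0.02, alpha=0.08)
        assert temperature_from_conductivity(0.0, m) == 0.0

    def test_pure_tc_linear_inversion(self):
        m = ConductivityChangeModel(tc=0.02, alpha=0.0)
        assert temperature_from_conductivity(0.04, m) == pytest.approx(2.0)

    def test_roundtrip_with_perfusion_curve(self):
        curve = PerfusionCurve(omega_max=6.0, t_plateau=45.0, t_onset=39.0)
        m = ConductivityChangeModel(tc=0.02, alpha=0.24)
        T = np.linspace(0.0, 8.0, 81)
        ds = conductivity_change(T, curve(37.0 + T), m)
        back = temperature_from_conductivity(ds, m, omega_curve=lambda t: curve(t))
        assert np.max(np.abs(back - T)) < 1e-5

    def test_out_of_range_clipped_and_flagged(self):
        curve = PerfusionCurve(omega_max=2.0)
        m = ConductivityChangeModel(tc=0.02, alpha=0.08)
        dt, flags = temperature_from_conductivity(
            np.array([10.0]), m, omega_curve=lambda t: curve(t), return_flags=True)
        assert flags[0] and dt[0] == pytest.approx(15.0)


class TestFieldsToSigma:
    def test_baseline_identity(self, small_setup):
        _, table, mesh, sigma = small_setup
        T = np.full(mesh.n_elements, 37.0)
        out = fields_to_sigma(T, np.ones(mesh.n_elements), sigma, mesh.labels, table)
        assert np.allclose(out.values, sigma.values)

    def test_uniform_tc_scaling(self, small_setup):
        _, table, mesh, sigma = small_setup
        T = np.full(mesh.n_elements, 42.0)
        out = fields_to_sigma(T, np.ones(mesh.n_elements), sigma, mesh.labels, table)
        assert np.allclose(out.values, sigma.values * 1.10, rtol=1e-12)

    def test_perfusion_term_skips_unresponsive_tissue(self, small_setup):
        _, table, mesh, sigma = small_setup
        T = np.full(mesh.n_elements, 42.0)
        omega = np.full(mesh.n_elements, 3.0)
        out = fields_to_sigma(T, omega, sigma, mesh.labels, table)
        bone = mesh.labels == table.id_of("bone")
        muscle = mesh.labels == table.id_of("muscle")
        assert np.allclose(out.values[bone], sigma.values[bone] * 1.10, rtol=1e-12)
        assert np.all(out.values[muscle] > sigma.values[muscle] * 1.10)


class TestTwoFrequencySeparation:
    def test_zero_changes(self):
        s = SeparationInputs(np.zeros(3), np.zeros(3))
        assert np.allclose(separate_temperature(s), 0.0)
        assert np.allclose(separate_perfusion(s), 1.0)

    def test_pure_temperature_case(self):
        # omega = 1, dT = 5: both frequencies see exactly Tc dT = 0.10
        s = SeparationInputs(np.array([0.10]), np.array([0.10]))
        assert separate_temperature(s)[0] == pytest.approx(5.0, rel=1e-12)
        assert separate_perfusion(s)[0] == pytest.approx(1.0, rel=1e-12)

    def test_forward_model_algebraic_cancellation(self):
        # dT = 4, omega = 4 -> dsigma_LF = 0.3392, dsigma_HF = 0.1664;
        # (3 * 0.1664 - 0.3392) / (2 * 0.02) = 4 exactly
        s = SeparationInputs(np.array([0.3392]), np.array([0.1664]))
        assert separate_temperature(s)[0] == pytest.approx(4.0, rel=1e-12)
        assert separate_perfusion(s)[0] == pytest.approx(4.0, rel=1e-12)

    def test_neglect_mode_bias(self):
        s = SeparationInputs(np.array([0.3392]), np.array([0.1664]))
        omega = separate_perfusion(s, delta_T="neglect")
        assert omega[0] == pytest.approx((1 + 0.1728 / 0.16) ** 2, rel=1e-12)
        assert omega[0] == pytest.approx(4.33, abs=0.005)

    def test_equal_alphas_rejected(self):
        with pytest.raises(ValueError):
            SeparationInputs(np.zeros(2), np.zeros(2), alpha_lf=0.1, alpha_hf=0.1)

    def test_exact_joint_recovery_on_grid(self):
        # the identity the separation relies on: exact inversion of the
        # forward model for any (dT, omega) with matching constants
        dT, om = np.meshgrid(np.linspace(0, 8, 17), np.linspace(1, 12, 23))
        dT, om = dT.ravel(), om.ravel()
        mlf = ConductivityChangeModel(tc=0.02, alpha=0.24)
        mhf = ConductivityChangeModel(tc=0.02, alpha=0.08)
        s = SeparationInputs(conductivity_change(dT, om, mlf),
                             conductivity_change(dT, om, mhf))
        dT_rec = separate_temperature(s)
        om_rec = separate_perfusion(s, delta_T=dT_rec)
        assert np.max(np.abs(dT_rec - dT)) < 1e-10 * max(1.0, np.max(np.abs(dT)))
        assert np.max(np.abs(om_rec - om)) < 1e-10 * np.max(om)

    def test_noise_amplification_asymmetry(self, rng):
        # with modest perfusion changes, independent conductivity noise
        # produces a larger relative error (w.r.t. the change magnitude) in
        # omega than in dT
        dT_true, om_true = 4.0, 1.5
        mlf = ConductivityChangeModel(tc=0.02, alpha=0.24)
        mhf = ConductivityChangeModel(tc=0.02, alpha=0.08)
        n = 20000
        noise = 0.002
        lf = conductivity_change(dT_true, om_true, mlf) + rng.normal(0, noise, n)
        hf = conductivity_change(dT_true, om_true, mhf) + rng.normal(0, noise, n)
        s = SeparationInputs(lf, hf)
        dT_rec = separate_temperature(s)
        om_rec = separate_perfusion(s, delta_T=np.full(n, dT_true))
        rel_T = np.std(dT_rec - dT_true) / dT_true
        rel_om = np.std(om_rec - om_true) / (om_true - 1.0)
        assert rel_om > rel_T
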