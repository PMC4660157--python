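import math
from dataclasses import replace

import numpy as np
import pytest

from runtumble.cascade import (CascadeEnsemble, CascadeError, CascadeParams,
                               CascadeState, ReceptorSpec, cascade_derivatives,
                               integrate_cascade, receptor_activity,
                               receptor_free_energy, scale_protein_totals,
                               sensitivity, steady_state, step_response)


class TestReceptor:
    def test_free_energy_single_species_hand_value(self):
        # pure-Tar team, f_m = 0 at m = methyl_offset: F = 6 ln(6/1.2)
        rec = ReceptorSpec(n_cluster=6, tar_fraction=1.0, tsr_fraction=0.0,
                           K_off_tar=0.02, K_on_tar=0.5)
        F = receptor_free_energy(rec, rec.methyl_offset, {"MeAsp": 0.1})
        assert F == pytest.approx(6 * math.log(6 / 1.2), rel=1e-12)

    def test_free_energy_reduces_to_methylation_term_without_ligand(self):
        rec = ReceptorSpec()
        for m in (0.0, 1.0, 2.5):
            F = receptor_free_energy(rec, m, {})
            assert F == pytest.approx(
                rec.n_cluster * rec.methyl_slope * (rec.methyl_offset - m))

    def test_negative_concentration_rejected(self):
        with pytest.raises(CascadeError):
            receptor_free_energy(ReceptorSpec(), 1.0, {"MeAsp": -0.1})

    def test_inverted_affinities_rejected(self):
        with pytest.raises(CascadeError):
            ReceptorSpec(K_off_tar=0.5, K_on_tar=0.02)

    @pytest.mark.parametrize("F, phi", [
        (0.0, 0.5), (math.log(3), 0.25), (700.0, 0.0), (-700.0, 1.0),
    ])
    def test_activity_closed_form(self, F, phi):
        assert receptor_activity(F) == pytest.approx(phi, abs=1e-12)

    def test_activity_strictly_decreasing(self):
        F = np.linspace(-30, 30, 301)
        phi = receptor_activity(F)
        assert np.all(np.diff(phi) < 0)


class TestDerivativesAndSteadyState:
    def test_zero_rates_give_zero_derivatives(self, background):
        p = CascadeParams(k_A=1e-300, k_y=1e-300, k_b=1e-300, k_z=1e-300,
                          gamma_Y=0.0, gamma_B=0.0, k_R=1e-300, k_B=1e-300)
        d = cascade_derivatives(CascadeState(1.0, 1.0, 0.5, 2.0), p, background)
        assert np.allclose(d.as_array(), 0.0, atol=1e-290)

    def test_steady_state_is_a_fixed_point(self, default_cascade, background):
        ss = steady_state(default_cascade, background)
        d = cascade_derivatives(ss, default_cascade, background)
        assert np.max(np.abs(d.as_array())) < 1e-9

    def test_steady_state_deterministic(self, default_cascade, background):
        a = steady_state(default_cascade, background)
        b = steady_state(default_cascade, background)
        assert a == b

    def test_phosphotransfer_vanishes_at_saturation(self, default_cascade,
                                                    background):
        p = default_cascade
        state = CascadeState(m=1.0, Ap=1.0, Bp=0.5, Yp=p.Y_T)
        d_full = cascade_derivatives(state, p, background)
        # at Yp = Y_T the transfer term is zero, so dYp/dt is pure loss
        assert d_full.Yp == pytest.approx(
            -(p.k_z * p.Z_T + p.gamma_Y) * p.Y_T)

    def test_doubling_totals_lowers_phosphorylated_fractions(
            self, default_cascade, background):
        ss1 = steady_state(default_cascade, background)
        ss2 = steady_state(scale_protein_totals(default_cascade, 2.0),
                           background)
        assert ss2.Yp / (2 * default_cascade.Y_T) < ss1.Yp / default_cascade.Y_T
        assert ss2.Ap / (2 * default_cascade.A_T) < ss1.Ap / default_cascade.A_T


class TestScaleProteinTotals:
    def test_identity_and_doubling(self, default_cascade):
        assert scale_protein_totals(default_cascade, 1.0) == default_cascade
        p2 = scale_protein_totals(default_cascade, 2.0)
        for name in ("A_T", "B_T", "R_T", "Y_T", "Z_T"):
            assert getattr(p2, name) == 2 * getattr(default_cascade, name)
        assert p2.k_y == default_cascade.k_y
        assert p2.receptor == default_cascade.receptor

    def test_round_trip(self, default_cascade):
        back = scale_protein_totals(
            scale_protein_totals(default_cascade, 4.0), 0.25)
        assert back == default_cascade

    def test_nonpositive_beta_rejected(self, default_cascade):
        with pytest.raises(CascadeError):
            scale_protein_totals(default_cascade, 0.0)


class TestIntegration:
    def test_zero_dt_is_identity(self, default_cascade, background,
                                 background_steady_state):
        out = integrate_cascade(background_steady_state, default_cascade,
                                background, 0.0)
        assert out == background_steady_state

    def test_steady_state_is_invariant_under_integration(
            self, default_cascade, background, background_steady_state):
        out = integrate_cascade(background_steady_state, default_cascade,
                                background, 10.0)
        assert np.allclose(out.as_array(),
                           background_steady_state.as_array(), rtol=1e-6)

    def test_step_input_dips_then_recovers(self, default_cascade):
        resp = step_response(default_cascade, (0.1, 0.2), t_max=600.0)
        assert resp.Yp_extremum < resp.Yp_pre          # immediate drop
        assert resp.amplitude > 0.01
        assert abs(resp.Yp_final - resp.Yp_pre) < 0.15 * resp.Yp_pre

    def test_bounds_preserved_along_trajectory(self, default_cascade):
        p = default_cascade
        state = steady_state(p, {"MeAsp": 0.1})
        for L in (0.2, 1.0, 0.05, 5.0):
            for _ in range(5):
                state = integrate_cascade(state, p, {"MeAsp": L}, 2.0)
                state.validate(p)

    def test_matches_rk4_reference_on_smooth_trajectory(self, default_cascade):
        # independent fixed-step 4th-order integration at dt/100
        p = default_cascade
        conc = {"MeAsp": 0.2}
        z0 = steady_state(p, {"MeAsp": 0.1}).as_array()

        def f(z):
            return cascade_derivatives(CascadeState.from_array(z), p,
                                       conc).as_array()

        dt = 0.05
        n_sub = 100
        h = dt / n_sub
        z = z0.copy()
        for _ in range(n_sub):
            k1 = f(z)
            k2 = f(z + 0.5 * h * k1)
            k3 = f(z + 0.5 * h * k2)
            k4 = f(z + h * k3)
            z = z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        lsoda = integrate_cascade(CascadeState.from_array(z0), p, conc, dt,
                                  rtol=1e-10, atol=1e-12).as_array()
        assert np.allclose(lsoda, z, rtol=1e-6)


class TestEnsembleIntegrator:
    def test_agrees_with_adaptive_reference(self, default_cascade):
        # three cells with different beta stepped 200x vs per-cell LSODA
        p = default_cascade
        betas = np.array([0.5, 1.0, 4.0])
        ens = CascadeEnsemble(p, betas)
        states = [steady_state(scale_protein_totals(p, b), {"MeAsp": 0.1})
                  for b in betas]
        z = np.stack([s.as_array() for s in states])
        z_ref = [s for s in states]
        dt = 0.0144
        conc = {"MeAsp": 0.35}
        for _ in range(200):
            z = ens.step(z, 0.35, 0.0, dt)
        for i, b in enumerate(betas):
            pb = scale_protein_totals(p, b)
            state = z_ref[i]
            for _ in range(10):   # 10 macro-steps of 0.288 s
                state = integrate_cascade(state, pb, conc, 20 * dt)
            assert z[i, 3] == pytest.approx(state.Yp, rel=2e-2)
            assert z[i, 0] == pytest.approx(state.m, rel=2e-3)

    def test_clamps_methylation_range(self, default_cascade):
        ens = CascadeEnsemble(default_cascade, np.array([1.0]))
        z = np.array([[default_cascade.receptor.m_max, 0.05, 1.0, 4.0]])
        out = ens.step(z, 1e3, 0.0, 1.0)   # huge attractant drives m up
        assert out[0, 0] <= default_cascade.receptor.m_max


class TestStepResponseDiagnostics:
    def test_zero_amplitude_step(self, default_cascade):
        resp = step_response(default_cascade, (0.1, 0.1))
        assert resp.adaptation_time == 0.0
        assert resp.amplitude == 0.0

    def test_adaptation_faster_and_shallower_at_high_beta(self,
                                                          default_cascade):
        lo = step_response(scale_protein_totals(default_cascade, 0.5),
                           (0.1, 0.2), t_max=1500.0)
        hi = step_response(scale_protein_totals(default_cascade, 2.0),
                           (0.1, 0.2), t_max=1500.0)
        assert hi.adaptation_time < lo.adaptation_time
        assert hi.amplitude_fraction < lo.amplitude_fraction


class TestSensitivity:
    def test_vanishes_at_extremes_and_positive_in_window(self,
                                                         default_cascade):
        S_low = sensitivity(default_cascade, 1e-6)
        S_mid = sensitivity(default_cascade, 0.1)
        S_high = sensitivity(default_cascade, 1e4)
        assert abs(S_low) < 1e-2
        assert abs(S_high) < 1e-2
        assert S_mid > 0.5

    def test_matches_analytic_mwc_derivative(self, default_cascade):
        # at fixed adapted m: S = (1-Phi) * n * w * (L/(L+Koff) - L/(L+Kon))
        p = default_cascade
        L = 0.1
        r = p.receptor
        ss = steady_state(p, {"MeAsp": L})
        phi = receptor_activity(receptor_free_energy(r, ss.m, {"MeAsp": L}))
        expected = (1 - phi) * r.n_cluster * r.tar_fraction * (
            L / (L + r.K_off_tar) - L / (L + r.K_on_tar))
        assert sensitivity(p, L) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_concentration_rejected(self, default_cascade):
        with pytest.raises(CascadeError):
            sensitivity(default_cascade, 0.0)
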