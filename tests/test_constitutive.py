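"""Constitutive laws: closed-form oracles, finite-difference consistency,
and the force-length/activation invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioloop.constitutive import (ActiveMaterialParams, ConstitutiveError,
                                     DeformationInvariants,
                                     PassiveMaterialParams, activation_phase,
                                     active_fiber_stress, eca50,
                                     effective_sarcomere_length,
                                     passive_energy, passive_stress_matrix,
                                     relaxation_duration)


def hand_energy(p, I1, I4f, I4s, I8fs):
    """Independent single-line evaluation of the strain-energy formula."""
    w = p.a / (2 * p.b) * np.exp(p.b * (I1 - 3))
    if I4f > 1:
        w += p.a_f / (2 * p.b_f) * (np.exp(p.b_f * (I4f - 1) ** 2) - 1)
    if I4s > 1:
        w += p.a_s / (2 * p.b_s) * (np.exp(p.b_s * (I4s - 1) ** 2) - 1)
    return w + p.a_fs / (2 * p.b_fs) * (np.exp(p.b_fs * I8fs ** 2) - 1)


class TestPassiveEnergy:
    def test_identity_energy_is_isotropic_offset(self, ventricle_passive):
        w = passive_energy(ventricle_passive, DeformationInvariants.identity())
        assert w == pytest.approx(3.9e-4 / 7.4, rel=1e-12)

    def test_uniaxial_fiber_stretch_matches_hand_evaluation(
            self, ventricle_passive):
        lam = 1.1
        inv = DeformationInvariants(I1=lam ** 2 + 2 / lam, I4f=lam ** 2,
                                    I4s=1 / lam, I8fs=0.0)
        expected = hand_energy(ventricle_passive, inv.I1, inv.I4f, inv.I4s, 0.0)
        assert passive_energy(ventricle_passive, inv) == pytest.approx(
            expected, rel=1e-12)

    def test_fiber_compression_switches_fiber_term_off(self, ventricle_passive):
        inv = DeformationInvariants(I1=3.0, I4f=0.9, I4s=1.0, I8fs=0.0)
        iso = DeformationInvariants.identity()
        assert passive_energy(ventricle_passive, inv) == pytest.approx(
            passive_energy(ventricle_passive, iso), rel=1e-12)

    def test_overflow_rejected_with_diagnostic(self, ventricle_passive):
        inv = DeformationInvariants(I1=3.0, I4f=400.0, I4s=1.0, I8fs=0.0)
        with pytest.raises(ConstitutiveError, match="fiber"):
            passive_energy(ventricle_passive, inv)

    def test_parameter_positivity_enforced(self):
        with pytest.raises(ConstitutiveError):
            PassiveMaterialParams(a=-1e-4, b=3.7, a_f=1.9e-3, b_f=14,
                                  a_s=1.1e-3, b_s=11, a_fs=3.6e-7, b_fs=7.8e-4)


def _C_from_stretches(lam_f, lam_s, lam_n):
    return np.diag([lam_f ** 2, lam_s ** 2, lam_n ** 2])


class TestPassiveStress:
    def test_zero_at_identity(self, ventricle_passive):
        S = passive_stress_matrix(ventricle_passive, np.eye(3))
        assert np.allclose(S, 0.0, atol=1e-15)

    def test_fiber_component_matches_isochoric_energy_gradient(
            self, ventricle_passive):
        # vary the fiber stretch, compensate with the sheet-normal so the
        # deformation stays isochoric at fixed sheet stretch
        lam_f, lam_s = 1.05, 1.01
        h = 1e-6

        def energy(lf):
            ln = 1.0 / (lf * lam_s)
            inv = DeformationInvariants(I1=lf ** 2 + lam_s ** 2 + ln ** 2,
                                        I4f=lf ** 2, I4s=lam_s ** 2, I8fs=0.0)
            return passive_energy(ventricle_passive, inv)

        # dPsi/dE_ff = (1/lam_f) dPsi/dlam_f along the isochoric path
        dpsi = (energy(lam_f + h) - energy(lam_f - h)) / (2 * h)
        expected_S_ff = dpsi / lam_f
        C = _C_from_stretches(lam_f, lam_s, 1.0 / (lam_f * lam_s))
        S = passive_stress_matrix(ventricle_passive, C)
        assert S[0, 0] == pytest.approx(expected_S_ff, rel=1e-6)
        assert S[2, 2] == pytest.approx(0.0, abs=1e-15)

    def test_fiber_stress_increases_with_tension(self, ventricle_passive):
        def s_ff(lam):
            C = _C_from_stretches(lam, 1.0, 1.0 / lam)
            return passive_stress_matrix(ventricle_passive, C)[0, 0]

        lams = np.linspace(1.0, 1.3, 16)
        vals = [s_ff(l) for l in lams]
        assert np.all(np.diff(vals) > 0)

    def test_gradient_consistency_at_random_admissible_states(
            self, ventricle_passive, rng):
        """Analytic stress equals the isochoric finite-difference gradient
        of the energy at 50 random states."""
        h = 1e-6
        for _ in range(50):
            lam_f = float(rng.uniform(0.95, 1.25))
            lam_s = float(rng.uniform(0.95, 1.25))
            lam_n = 1.0 / (lam_f * lam_s)
            C = _C_from_stretches(lam_f, lam_s, lam_n)
            S = passive_stress_matrix(ventricle_passive, C)

            def energy(lf, ls):
                ln = 1.0 / (lf * ls)
                inv = DeformationInvariants(I1=lf ** 2 + ls ** 2 + ln ** 2,
                                            I4f=lf ** 2, I4s=ls ** 2, I8fs=0.0)
                return passive_energy(ventricle_passive, inv)

            d_f = (energy(lam_f + h, lam_s) - energy(lam_f - h, lam_s)) / (2 * h)
            d_s = (energy(lam_f, lam_s + h) - energy(lam_f, lam_s - h)) / (2 * h)
            assert S[0, 0] * lam_f == pytest.approx(d_f, rel=2e-5, abs=1e-10)
            assert S[1, 1] * lam_s == pytest.approx(d_s, rel=2e-5, abs=1e-10)


class TestSarcomereKinematics:
    @pytest.mark.parametrize("Eff, lr, expected", [
        (0.0, 0.00185, 0.00185),
        (0.06245, 0.00185, 0.00185 * np.sqrt(1.1249)),
    ])
    def test_effective_length_values(self, Eff, lr, expected):
        assert effective_sarcomere_length(Eff, lr) == pytest.approx(
            expected, rel=1e-12)

    def test_degenerate_strain_rejected(self):
        with pytest.raises(ConstitutiveError):
            effective_sarcomere_length(-0.5, 0.00185)

    @pytest.mark.parametrize("l, m, b, expected", [
        (0.00185, 950.0, -1.5, 0.2575),
        (0.00158, 950.0, -1.5, 0.001),
        (0.5, 0.0, 0.3, 0.3),
    ])
    def test_relaxation_duration_values(self, l, m, b, expected):
        assert relaxation_duration(l, m, b) == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(ConstitutiveError):
            relaxation_duration(0.001, 950.0, -1.5)


class TestActivationPhase:
    def test_zero_at_onset(self):
        assert activation_phase(0.0, 0.35, 0.25) == 0.0

    def test_continuous_at_peak(self):
        t0, tr = 0.35, 0.2575
        eps = 1e-9
        below = activation_phase(t0 - eps, t0, tr)
        above = activation_phase(t0 + eps, t0, tr)
        assert below == pytest.approx(np.pi, abs=1e-7)
        assert above == pytest.approx(np.pi, abs=1e-7)

    def test_mid_relaxation_phase_and_zero_closure(self):
        t0, tr = 0.35, 0.2575
        omega = activation_phase(t0 + tr / 2, t0, tr)
        assert omega == pytest.approx(1.5 * np.pi, rel=1e-12)
        # the (1 - cos) envelope closes exactly at the end of relaxation
        assert 1 - np.cos(activation_phase(t0 + tr, t0, tr)) \
            == pytest.approx(0.0, abs=1e-12)


class TestCalciumSensitivity:
    def test_value_at_resting_length(self, ventricle_active):
        a = ventricle_active
        expected = a.Ca0max / np.sqrt(np.exp(a.B * (a.lr - a.l0)) - 1.0)
        assert eca50(a, a.lr) == pytest.approx(expected, rel=1e-12)
        assert eca50(a, a.lr) == pytest.approx(2.695, rel=1e-3)

    def test_limits(self, ventricle_active):
        a = ventricle_active
        assert eca50(a, a.l0 * (1 + 1e-12)) > 1e3
        assert eca50(a, 10 * a.lr) < 1e-3

    def test_monotone_decreasing_in_length(self, ventricle_active):
        ls = np.linspace(0.0017, 0.0025, 30)
        vals = eca50(ventricle_active, ls)
        assert np.all(np.diff(vals) < 0)


class TestActiveFiberStress:
    def test_zero_at_onset(self, ventricle_active):
        assert active_fiber_stress(0.0, 0.1, ventricle_active) == 0.0

    def test_peak_value_at_t0(self, ventricle_active):
        sigma = active_fiber_stress(0.35, 0.0, ventricle_active)
        assert sigma == pytest.approx(0.1445, abs=2e-4)

    def test_linear_in_tmax(self, ventricle_active):
        doubled = ventricle_active.with_tmax(0.4)
        s1 = active_fiber_stress(0.35, 0.0, ventricle_active)
        s2 = active_fiber_stress(0.35, 0.0, doubled)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)

    def test_zero_below_slack_length_and_after_window(self, ventricle_active):
        a = ventricle_active
        # l_eff <= l0: no force regardless of activation
        Eff_low = 0.5 * ((a.l0 / a.lr) ** 2 - 1) - 0.01
        assert active_fiber_stress(a.t0, Eff_low, a) == 0.0
        # beyond t0 + tr: relaxed
        tr = a.m * a.lr + a.b_relax
        assert active_fiber_stress(a.t0 + tr + 1e-9, 0.0, a) == 0.0

    @settings(deadline=None, max_examples=60)
    @given(t=st.floats(0.0, 1.2), Eff=st.floats(-0.49, 0.3))
    def test_bounded_and_nonnegative(self, t, Eff):
        a = ActiveMaterialParams.ventricle()
        sigma = active_fiber_stress(t, Eff, a)
        assert 0.0 <= sigma <= a.Tmax + 1e-15

    def test_frank_starling_monotone_in_strain_at_peak(self, ventricle_active):
        Effs = np.linspace(0.0, 0.15, 25)
        sig = active_fiber_stress(0.35, Effs, ventricle_active)
        assert np.all(np.diff(sig) >= -1e-15)
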