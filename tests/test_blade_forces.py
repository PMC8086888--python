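"""Blade-element states, force laws and stroke-averaged summations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import flapforce as ff
from flapforce.bladeforces import (Coefficients, added_mass_normal,
                                   added_mass_parallel_oracle,
                                   coefficient_curves, element_state,
                                   predict_stroke_force, quasi_steady_forces,
                                   stroke_sums, wing_states)
from flapforce.kinematics import N_PHASE, WingbeatFrame
from flapforce.morphology import WingPlanform, discretize_planform

from conftest import static_frame


def _states(frame, side="right", planform=None, n=20, f_ref=0.75):
    pf = planform
    els = discretize_planform(pf, n)
    return wing_states(frame, side, els, pf.wing_base_offset, f_ref)


class TestElementState:
    def test_pure_translation_chord_parallel(self, translation_frame,
                                             rect_planform):
        st = _states(translation_frame, planform=rect_planform)
        assert np.max(st.alpha) == 0.0
        assert np.allclose(st.U, 1.0)

    def test_pure_translation_chord_perpendicular(self, rect_planform):
        frame = static_frame(chord_pitch=np.pi / 2, body_vel=(-1, 0, 0))
        st = _states(frame, planform=rect_planform)
        assert np.allclose(st.alpha, np.pi / 2)

    def test_chain_matches_finite_difference_oracle(self, gen_params,
                                                    planforms):
        """Velocity/acceleration of the chain vs central differences of the
        independently posed position chain."""
        from scipy.spatial.transform import Rotation
        from flapforce.synthetic import _body_motion, _wing_channels

        p = ff.GeneratorParams(body_programme="const_accel")
        frame = ff.analytic_frames(p, n_wingbeats=1)[0]
        t = frame.t
        # add body yaw oscillation so the body rotation rates matter
        frame.euler[:, 0] = 0.2 * np.sin(2 * np.pi * 50 * t)
        frame.euler_d[:, 0] = 0.2 * 2 * np.pi * 50 * np.cos(2 * np.pi * 50
                                                            * t)
        frame.euler_dd[:, 0] = -0.2 * (2 * np.pi * 50) ** 2 \
            * np.sin(2 * np.pi * 50 * t)
        els = discretize_planform(planforms["right"], 4)

        def positions(tq, side, d_attr):
            phi, theta, om0, omr = _wing_channels(tq, p)
            pos, _, _ = _body_motion(tq, p)
            yaw = 0.2 * np.sin(2 * np.pi * 50 * tq)
            M = np.diag([1, -1, 1]) if side == "left" else np.eye(3)
            base = planforms[side].wing_base_offset
            out = []
            for j in range(len(tq)):
                Rb = Rotation.from_euler(
                    "ZYX", [yaw[j], -np.deg2rad(43.6), 0]).as_matrix()
                pts = []
                for g in els:
                    om = om0[0][j] + omr[0][j] * g.r
                    Rs = (Rotation.from_euler("z", phi[0][j]).as_matrix()
                          @ Rotation.from_euler("x", theta[0][j]).as_matrix())
                    Rp = Rotation.from_euler("y", om).as_matrix()
                    d = g.d_ref(0.75) if d_attr == "ref" else g.d_half
                    X = (pos[j] + Rb @ base + Rb @ M @ Rs
                         @ np.array([0, g.r, 0])
                         + Rb @ M @ Rs @ Rp @ np.array([-d, 0, 0]))
                    pts.append(X)
                out.append(pts)
            return np.array(out)

        h = 1e-7
        for side in ("right", "left"):
            st = wing_states(frame, side, els,
                             planforms[side].wing_base_offset)
            for tau in (0, 25, 63):
                tq = np.array([t[tau] - h, t[tau], t[tau] + h])
                P = positions(tq, side, "ref")
                v_fd = (P[2] - P[0]) / (2 * h)
                scale = np.abs(st.vel_ref[tau]).max()
                assert np.abs(v_fd - st.vel_ref[tau]).max() < 1e-6 * scale
                Ph = positions(tq, side, "half")
                a_fd = (Ph[2] - 2 * Ph[1] + Ph[0]) / h**2
                scale = np.abs(st.acc_half[tau]).max()
                assert np.abs(a_fd - st.acc_half[tau]).max() < 1e-5 * scale

    def test_scalar_wrapper_matches_vectorized(self, hover_frame, planforms):
        els = discretize_planform(planforms["right"], 20)
        st = wing_states(hover_frame, "right", els,
                         planforms["right"].wing_base_offset)
        s = element_state(hover_frame, "right", els[9], 25,
                          planforms["right"].wing_base_offset)
        assert s.U == pytest.approx(st.U[25, 9])
        assert s.alpha == pytest.approx(st.alpha[25, 9])
        assert np.allclose(s.u_norm, st.u_norm[25, 9])

    def test_degenerate_flow_flagged(self, rect_planform):
        frame = static_frame(body_vel=(0, 0, 0))
        st = _states(frame, planform=rect_planform)
        assert st.degenerate.all()
        L, D = quasi_steady_forces(st, Coefficients(2.7, 0.15))
        assert np.all(L == 0) and np.all(D == 0)


class TestGeometryInvariants:
    """Unit-vector identities at every evaluated state (manoeuvring data)."""

    @pytest.fixture
    def states(self, manoeuvre_frames, planforms):
        frame = manoeuvre_frames[3]
        els = discretize_planform(planforms["right"], 20)
        return wing_states(frame, "right", els,
                           planforms["right"].wing_base_offset)

    def test_unit_norms(self, states):
        for v in (states.u_par, states.u_perp, states.u_norm):
            assert np.abs(np.linalg.norm(v, axis=-1) - 1.0).max() < 1e-12

    def test_surface_normal_identity(self, states):
        """1_perpS = 1_perpU cos a + 1_parU sin a at every state."""
        rhs = (states.u_perp * np.cos(states.alpha)[..., None]
               + states.u_par * np.sin(states.alpha)[..., None])
        assert np.abs(states.u_norm - rhs).max() < 1e-12

    def test_lift_perpendicular_drag_opposing(self, states):
        L, D = quasi_steady_forces(states, Coefficients(2.7, 0.15))
        v = states.vel_ref
        vnorm = np.linalg.norm(v, axis=-1)
        Lnorm = np.linalg.norm(L, axis=-1)
        dot = np.einsum("pei,pei->pe", L, v)
        mask = Lnorm > 0
        assert np.abs(dot[mask] / (Lnorm[mask] * vnorm[mask])).max() < 1e-12
        assert np.all(np.einsum("pei,pei->pe", D, v) <= 1e-15)

    def test_perp_orthogonal_to_span(self, states):
        dot = np.einsum("pei,pei->pe", states.u_perp, states.span)
        assert np.abs(dot).max() < 1e-12

    def test_drag_direction_is_relative_flow(self, states):
        mask = ~states.degenerate
        w_p = -(states.vel_ref - np.einsum(
            "pei,pei->pe", states.vel_ref, states.span)[..., None]
            * states.span)
        cos = np.einsum("pei,pei->pe", states.u_par, w_p) \
            / np.linalg.norm(w_p, axis=-1)
        assert np.all(cos[mask] > 1.0 - 1e-12)


class TestForceLaws:
    def _unit_state_frame(self, rect_planform, alpha):
        """Pure translation at speed 1 with chord pitched to give alpha."""
        return static_frame(chord_pitch=alpha, body_vel=(-1.0, 0.0, 0.0))

    def test_lift_hand_value(self, rect_planform):
        # alpha = 45 deg, U = 1, C_Pa = 2.70: |L| = 1/2 rho U^2 c dr * 1.35
        frame = self._unit_state_frame(rect_planform, np.pi / 4)
        pf = WingPlanform(length=1.0, r=[0, 1.0], chord=[1.0, 1.0],
                          axis_offset_le=[0.0, 0.0])
        frame.rho = 2.0
        els = discretize_planform(pf, 1)
        st = wing_states(frame, "right", els, np.zeros(3))
        L, D = quasi_steady_forces(st, Coefficients(2.70, 0.0))
        assert np.linalg.norm(L[0, 0]) == pytest.approx(1.35, rel=1e-12)

    def test_zero_alpha_only_offset_drag(self):
        frame = static_frame(body_vel=(-1.0, 0, 0))
        frame.rho = 2.0
        pf = WingPlanform(length=1.0, r=[0, 1.0], chord=[1.0, 1.0],
                          axis_offset_le=[0.0, 0.0])
        els = discretize_planform(pf, 1)
        st = wing_states(frame, "right", els, np.zeros(3))
        L, D = quasi_steady_forces(st, Coefficients(2.70, 0.15))
        assert np.linalg.norm(L[0, 0]) == pytest.approx(0.0, abs=1e-15)
        assert np.linalg.norm(D[0, 0]) == pytest.approx(0.15, rel=1e-12)

    def test_zero_speed_zero_quasi_steady(self, rect_planform):
        st = _states(static_frame(), planform=rect_planform)
        L, D = quasi_steady_forces(st, Coefficients(2.7, 0.15))
        assert np.all(L == 0) and np.all(D == 0)

    def test_added_mass_closed_form_magnitude(self):
        """a_norm = 1, c = 1, dr = 1, rho = 4/pi gives exactly 1 N."""
        frame = static_frame(body_vel=(-1e-3, 0, 0), body_acc=(0, 0, -1.0))
        frame.rho = 4.0 / np.pi
        pf = WingPlanform(length=1.0, r=[0, 1.0], chord=[1.0, 1.0],
                          axis_offset_le=[0.5, 0.5])
        els = discretize_planform(pf, 1)
        st = wing_states(frame, "right", els, np.zeros(3))
        A = added_mass_normal(st)
        # acceleration is purely surface-normal here (flat wing, -z accel)
        assert np.linalg.norm(A[0, 0]) == pytest.approx(1.0, rel=1e-9)
        # force opposes the normal acceleration
        assert A[0, 0, 2] > 0

    def test_added_mass_zero_without_normal_acceleration(self,
                                                         rect_planform):
        st = _states(static_frame(body_vel=(-1, 0, 0)),
                     planform=rect_planform)
        assert np.abs(st.a_norm).max() < 1e-12
        assert np.abs(added_mass_normal(st)).max() < 1e-12

    def test_chordwise_acceleration_gives_no_added_mass(self, rect_planform):
        # plate accelerating purely parallel to its chord (along x)
        st = _states(static_frame(body_vel=(-1, 0, 0), body_acc=(2, 0, 0)),
                     planform=rect_planform)
        assert np.abs(added_mass_normal(st)).max() < 1e-12


class TestAddedMassParallel:
    def _pitch_plunge_frame(self, with_pitch=True, with_plunge=True):
        T = 0.01
        t = np.arange(N_PHASE) / N_PHASE * T
        w = 2 * np.pi / T
        zz = np.zeros(N_PHASE)
        om = 0.3 + (0.6 * np.sin(w * t + 0.7) if with_pitch else 0.0)
        om_d = 0.6 * w * np.cos(w * t + 0.7) if with_pitch else zz
        om_dd = -0.6 * w**2 * np.sin(w * t + 0.7) if with_pitch else zz
        h = 0.003 * np.sin(w * t) if with_plunge else zz
        pos = np.zeros((N_PHASE, 3))
        vel = np.zeros((N_PHASE, 3))
        acc = np.zeros((N_PHASE, 3))
        pos[:, 2] = h
        vel[:, 2] = 0.003 * w * np.cos(w * t) if with_plunge else 0
        acc[:, 2] = -0.003 * w**2 * np.sin(w * t) if with_plunge else 0
        wing = {"phi": zz, "phi_d": zz, "phi_dd": zz, "theta": zz,
                "theta_d": zz, "theta_dd": zz,
                "omega0": om if with_pitch else np.full(N_PHASE, 0.3),
                "omega0_d": om_d, "omega0_dd": om_dd,
                "omega_r": zz, "omega_r_d": zz, "omega_r_dd": zz}
        return WingbeatFrame(
            n=0, t=t, period=T, body_pos=pos, body_vel=vel, body_acc=acc,
            euler=np.zeros((N_PHASE, 3)), euler_d=np.zeros((N_PHASE, 3)),
            euler_dd=np.zeros((N_PHASE, 3)),
            wings={"left": wing, "right": wing}, mass=1e-4, rho=1.2)

    @pytest.fixture
    def plate(self):
        return WingPlanform(length=0.01, r=[0, 0.01], chord=[0.003, 0.003],
                            axis_offset_le=[0.0009, 0.0009])

    def test_zero_pitch_rate_gives_zero(self, plate):
        st = _states(self._pitch_plunge_frame(with_pitch=False),
                     planform=plate, n=1)
        assert np.abs(added_mass_parallel_oracle(st)).max() < 1e-15

    def test_zero_normal_velocity_gives_zero(self, plate):
        # chordwise slicing: pitch rate without plunge, plate untwisted and
        # not translating normal to itself
        frame = self._pitch_plunge_frame(with_plunge=False)
        st = _states(frame, planform=plate, n=1)
        # normal velocity of the half-chord point comes only from rotation
        # about the axis; for the axis at 30% chord it is small but nonzero,
        # so test the algebraic structure instead at masked samples
        A = added_mass_parallel_oracle(st)
        mask = np.abs(st.U_perpS_half) < 1e-12
        if mask.any():
            assert np.abs(A[mask]).max() < 1e-15
        # and the magnitude follows (pi/4) rho c^2 |Omega_r U'_perpS| dr
        expect = (np.pi / 4) * st.rho * st.chord[None, :] ** 2 \
            * np.abs(st.omega_pitch * st.U_perpS_half) * st.dr
        assert np.allclose(np.linalg.norm(A, axis=-1), expect, rtol=1e-10)

    def test_periodic_cycle_closure(self, plate):
        """Normal + chordwise added mass integrate to ~zero over one period;
        the normal component alone does not."""
        st = _states(self._pitch_plunge_frame(), planform=plate, n=1)
        An = added_mass_normal(st)
        Ap = added_mass_parallel_oracle(st)
        peak = np.linalg.norm(An + Ap, axis=-1).max()
        total = np.abs((An + Ap).mean(axis=(0, 1)))
        assert total.max() / peak < 1e-6
        normal_only = np.abs(An.mean(axis=(0, 1)))
        assert normal_only.max() / peak > 1e-3


class TestStrokeSums:
    def test_static_wing_all_zero(self, rect_planform):
        st = _states(static_frame(), planform=rect_planform)
        s = stroke_sums(st)
        for v in (s.sigma_P, s.sigma_D, s.sigma_A):
            assert np.abs(v).max() < 1e-15

    def test_trigonometric_collapse(self, hover_frame, planforms):
        """C_Pa Sigma_P + C_D0 Sigma_D equals the direct lift+drag sum."""
        st = _states(hover_frame, planform=planforms["right"])
        coeffs = Coefficients(2.7, 0.15)
        L, D = quasi_steady_forces(st, coeffs)
        direct = (L + D).sum(axis=(0, 1)) / N_PHASE
        s = stroke_sums(st)
        collapsed = coeffs.C_P_alpha * s.sigma_P + coeffs.C_D0 * s.sigma_D
        assert np.abs(direct - collapsed).max() < 1e-12 * np.abs(direct).max()

    def test_mirror_symmetry_zero_lateral(self, hover_frame, planforms):
        sums = ff.frame_stroke_sums(hover_frame, planforms)
        combined = ff.predict_stroke_force(sums["LR"],
                                           Coefficients(2.7, 0.15))
        assert abs(combined[1]) < 1e-10 * np.linalg.norm(combined)

    def test_predict_linearity(self, hover_frame, planforms):
        sums = ff.frame_stroke_sums(hover_frame, planforms)["LR"]
        f0 = predict_stroke_force(sums, Coefficients(0.0, 0.0))
        assert np.allclose(f0, sums.sigma_A)
        # doubling C_Pa doubles the Sigma_P contribution exactly
        f1 = predict_stroke_force(sums, Coefficients(1.3, 0.2))
        f2 = predict_stroke_force(sums, Coefficients(2.6, 0.2))
        contrib1 = f1 - sums.sigma_A - 0.2 * sums.sigma_D
        contrib2 = f2 - sums.sigma_A - 0.2 * sums.sigma_D
        assert np.allclose(contrib2, 2 * contrib1, rtol=1e-14)


class TestCoefficientCurves:
    def test_standard_coefficient_values_at_key_angles(self):
        coeffs = Coefficients(2.70, 0.15)
        C_L, C_D, gamma = coefficient_curves(np.pi / 4, coeffs)
        assert C_L == pytest.approx(1.35)
        C_L0, C_D0, gamma0 = coefficient_curves(0.0, coeffs)
        assert C_L0 == 0.0
        assert C_D0 == pytest.approx(0.15)
        assert gamma0 == 0.0

    def test_gamma_ninety_degrees_without_offset(self):
        coeffs = Coefficients(2.70, 0.0)
        alpha = np.linspace(0.01, np.pi / 2 - 0.01, 50)
        _, _, gamma = coefficient_curves(alpha, coeffs)
        assert np.allclose(gamma, np.pi / 2, atol=1e-12)

    def test_double_angle_identity(self):
        """C_L = (C_Pa/2) sin 2a; C_D = (C_D0 + C_Pa/2) - (C_Pa/2) cos 2a."""
        coeffs = Coefficients(2.70, 0.15)
        alpha = np.linspace(0, np.pi / 2, 181)
        C_L, C_D, _ = coefficient_curves(alpha, coeffs)
        assert np.allclose(C_L, 1.35 * np.sin(2 * alpha), atol=1e-14)
        assert np.allclose(C_D, 1.50 - 1.35 * np.cos(2 * alpha), atol=1e-14)

    def test_alpha_out_of_range_raises(self):
        with pytest.raises(ValueError):
            coefficient_curves(-0.2, Coefficients(2.7, 0.15))
        with pytest.raises(ValueError):
            coefficient_curves(2.0, Coefficients(2.7, 0.15))


class TestCoefficientCurveProperties:
    """Property-based checks of the polar identities."""

    @given(cpa=hst.floats(0.0, 10.0), cd0=hst.floats(0.0, 2.0),
           alpha=hst.floats(0.0, np.pi / 2))
    @settings(derandomize=True, max_examples=200)
    def test_double_angle_form_holds_everywhere(self, cpa, cd0, alpha):
        coeffs = Coefficients(cpa, cd0)
        C_L, C_D, gamma = coefficient_curves(alpha, coeffs)
        assert C_L == pytest.approx((cpa / 2) * np.sin(2 * alpha), abs=1e-12)
        assert C_D == pytest.approx((cd0 + cpa / 2)
                                    - (cpa / 2) * np.cos(2 * alpha),
                                    abs=1e-12)
        assert 0.0 <= gamma <= np.pi + 1e-12
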