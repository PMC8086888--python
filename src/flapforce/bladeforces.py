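"""Blade-element aerodynamic states and force laws.

Each wing is treated as 20 independent chordwise blade elements.  At every
phase sample the rigid kinematic chain

    lab  <-  body (yaw-pitch-roll)  <-  wing base  <-  stroke (phi) and
    deviation (theta) rotations  <-  spanwise pitch omega(r) = omega0 +
    omega_r * r

is differentiated analytically (twice) to give the lab-frame velocity of the
chordwise reference point (default: three-quarter chord) and the acceleration
of the half-chord point.  From these, the quasi-steady pressure lift and drag

    L = 1/2 rho U^2 c (C_Pa sin a cos a) u_perp dr
    D = 1/2 rho U^2 c (C_Pa sin^2 a + C_D0) u_par dr

and the thin-plate added-mass force

    A = -(pi/4) rho c^2 a_norm u_norm dr

are evaluated, where U and the angle of attack a are measured in the plane
perpendicular to the span, u_par points along the relative flow, u_perp is
the lift direction (perpendicular to flow and span, toward increasing a) and
u_norm is the chord-plane normal signed toward the suction side, satisfying
u_norm = u_perp cos a + u_par sin a.

The surface-normal acceleration a_norm is the inertial-frame rate of change
of the surface-normal velocity of the half-chord point,
``d/dt (u_norm . v) = u_norm . a + Omega_r (s x u_norm) . v``; the rotation
coupling term vanishes for a non-pitching element and makes the combined
normal + chordwise added-mass force the exact rate of change of the fluid
momentum, so that it integrates to zero over any strictly periodic rigid
planar motion.  Only the surface-normal component enters the predicted
forces; the chordwise component is provided separately as a validation
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import WingbeatFrame
from .morphology import BladeElementGeometry, WingPlanform, discretize_planform
from .rotations import compose, euler_zyx_derivs, rot_derivs

__all__ = [
    "Coefficients",
    "BladeElementState",
    "ElementStates",
    "StrokeSums",
    "wing_states",
    "element_state",
    "quasi_steady_forces",
    "added_mass_normal",
    "added_mass_parallel_oracle",
    "stroke_sums",
    "predict_stroke_force",
    "coefficient_curves",
]

DEGENERATE_SPEED = 1e-6  # m/s; below this the quasi-steady force is dropped

_MIRROR = np.diag([1.0, -1.0, 1.0])  # body x-z plane reflection
_CHORD0 = np.array([-1.0, 0.0, 0.0])  # chord unit at zero pitch, LE -> TE


@dataclass(frozen=True)
class Coefficients:
    """The two fitted aerodynamic parameters of the model.

    ``C_P_alpha`` is the derivative of the pressure-force coefficient with
    respect to angle of attack at zero incidence; ``C_D0`` is the drag
    coefficient offset at zero incidence (friction plus residual pressure
    drag).  ``f_ref`` is the chord fraction, back from the leading edge, at
    which the aerodynamic speed and angle of attack are measured.
    """

    C_P_alpha: float
    C_D0: float = 0.0
    f_ref: float = 0.75

    def __post_init__(self):
        if self.C_D0 < 0:
            raise ValueError("C_D0 must be non-negative")
        if not 0.0 <= self.f_ref <= 1.0:
            raise ValueError("f_ref must lie in [0, 1]")


@dataclass
class ElementStates:
    """Vectorized aerodynamic state for one wing over a whole wingbeat.

    All leading array dimensions are ``(n_phase, n_elements)``.
    """

    U: np.ndarray  # in-plane speed at the reference point
    alpha: np.ndarray  # angle of attack in [0, pi/2]
    U_parc: np.ndarray  # chordwise velocity component magnitude basis
    U_perpS: np.ndarray  # surface-normal velocity component at ref point
    u_par: np.ndarray  # (..., 3) drag direction (relative flow)
    u_perp: np.ndarray  # (..., 3) lift direction
    u_norm: np.ndarray  # (..., 3) signed surface normal
    a_norm: np.ndarray  # surface-normal acceleration at half chord
    omega_pitch: np.ndarray  # spanwise pitch rate Omega_r
    U_perpS_half: np.ndarray  # surface-normal velocity at half chord
    span: np.ndarray  # (..., 3) spanwise unit vector
    chord_dir: np.ndarray  # (..., 3) chord unit vector, LE -> TE
    vel_ref: np.ndarray  # (..., 3) lab velocity of the reference point
    acc_half: np.ndarray  # (..., 3) lab acceleration of the half-chord point
    degenerate: np.ndarray  # bool mask: in-plane flow below threshold
    chord: np.ndarray  # (n_elements,)
    dr: float
    rho: float


@dataclass
class BladeElementState:
    """Scalar aerodynamic state of one blade element at one instant."""

    U: float
    alpha: float
    U_parc: float
    U_perpS: float
    u_par: np.ndarray
    u_perp: np.ndarray
    u_norm: np.ndarray
    a_norm: float
    omega_pitch: float
    U_perpS_half: float
    span: np.ndarray
    chord_dir: np.ndarray
    degenerate: bool


def _unit(v, axis=-1):
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.where(n > 0, n, 1.0)


def wing_states(frame: WingbeatFrame, side: str,
                elements: list[BladeElementGeometry],
                wing_base_offset=None,
                f_ref: float = 0.75) -> ElementStates:
    """Aerodynamic state of every blade element at every phase sample.

    The left wing is handled by mirroring the (right-handed) stroke chain
    through the body x-z plane, so a single code path serves both sides.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if not 0.0 <= f_ref <= 1.0:
        raise ValueError("f_ref must lie in [0, 1]")
    w = frame.wings[side]
    r_i = np.array([g.r for g in elements])
    c_i = np.array([g.chord for g in elements])
    d_ref = np.array([g.d_ref(f_ref) for g in elements])
    d_half = np.array([g.d_half for g in elements])
    dr = elements[0].dr
    if wing_base_offset is None:
        wing_base_offset = np.zeros(3)
    base = np.asarray(wing_base_offset, dtype=float)

    # rotation triples ------------------------------------------------------
    Tb = euler_zyx_derivs(frame.euler, frame.euler_d, frame.euler_dd)
    Ts = compose(rot_derivs("z", w["phi"], w["phi_d"], w["phi_dd"]),
                 rot_derivs("x", w["theta"], w["theta_d"], w["theta_dd"]))
    if side == "left":
        # left-handed wing frame: insert the x-z reflection after the body
        # rotation, so the chain becomes R_b M R_s R_p.  The stored base
        # offset is a physical body-frame vector, so pre-reflect it to cancel
        # the M now carried inside Tb.
        Tb = tuple(M @ _MIRROR for M in Tb)
        base = _MIRROR @ base
    A = compose(Tb, Ts)  # body+stroke orientation, (100, 3, 3) triple

    # per-element pitch angle and rates: omega(r_i) = omega0 + omega_r r_i
    om = w["omega0"][:, None] + w["omega_r"][:, None] * r_i[None, :]
    om_d = w["omega0_d"][:, None] + w["omega_r_d"][:, None] * r_i[None, :]
    om_dd = w["omega0_dd"][:, None] + w["omega_r_dd"][:, None] * r_i[None, :]
    Tp = rot_derivs("y", om, om_d, om_dd)  # (100, n, 3, 3) triple
    A_b = tuple(M[:, None] for M in A)
    E = compose(A_b, Tp)  # full element orientation triple

    # kinematic chain: X = X_b + R_b base + A (r y) + E (d c0) -------------
    Rb, Rbd, Rbdd = Tb
    A0, Ad, Add = A
    E0, Ed, Edd = E
    span = A0[:, :, 1][:, None, :] * np.ones_like(r_i)[None, :, None]
    chord_dir = E0 @ _CHORD0  # (100, n, 3)

    def point_vel_acc(d):
        vel = (frame.body_vel[:, None, :]
               + (Rbd @ base)[:, None, :]
               + r_i[None, :, None] * Ad[:, :, 1][:, None, :]
               + d[None, :, None] * (Ed @ _CHORD0))
        acc = (frame.body_acc[:, None, :]
               + (Rbdd @ base)[:, None, :]
               + r_i[None, :, None] * Add[:, :, 1][:, None, :]
               + d[None, :, None] * (Edd @ _CHORD0))
        return vel, acc

    vel_ref, _ = point_vel_acc(d_ref)
    vel_half, acc_half = point_vel_acc(d_half)

    # angular pitch rate about the spanwise axis ---------------------------
    W = Ed @ np.swapaxes(E0, -1, -2)
    omega_vec = np.stack(
        [W[..., 2, 1] - W[..., 1, 2],
         W[..., 0, 2] - W[..., 2, 0],
         W[..., 1, 0] - W[..., 0, 1]], axis=-1) / 2.0
    omega_pitch = np.einsum("pei,pei->pe", omega_vec, span)

    # relative wind with the spanwise component removed --------------------
    wind = -vel_ref
    w_p = wind - np.einsum("pei,pei->pe", wind, span)[..., None] * span
    U = np.linalg.norm(w_p, axis=-1)
    degenerate = U < DEGENERATE_SPEED
    u_par = _unit(w_p)

    U_parc = np.einsum("pei,pei->pe", w_p, chord_dir)
    n_geo = np.cross(chord_dir, span)  # unit: chord and span orthonormal
    U_perpS_geo = np.einsum("pei,pei->pe", w_p, n_geo)
    sign = np.where(U_perpS_geo >= 0, 1.0, -1.0)
    u_norm = sign[..., None] * n_geo

    cos_a = np.clip(np.abs(U_parc) / np.where(U > 0, U, 1.0), 0.0, 1.0)
    alpha = np.where(degenerate, 0.0, np.arccos(cos_a))

    q = np.cross(span, u_par)
    q_sign = np.where(np.einsum("pei,pei->pe", q, u_norm) >= 0, 1.0, -1.0)
    u_perp = q_sign[..., None] * q

    # surface-normal acceleration at the half-chord point (inertial rate of
    # change of the normal velocity; see module docstring)
    sxn = np.cross(span, u_norm)
    a_norm = (np.einsum("pei,pei->pe", acc_half, u_norm)
              + omega_pitch * np.einsum("pei,pei->pe", vel_half, sxn))
    U_perpS_half = np.einsum("pei,pei->pe", vel_half, u_norm)
    U_perpS = np.abs(U_perpS_geo)

    return ElementStates(
        U=U, alpha=alpha, U_parc=np.abs(U_parc), U_perpS=U_perpS,
        u_par=u_par, u_perp=u_perp, u_norm=u_norm, a_norm=a_norm,
        omega_pitch=omega_pitch, U_perpS_half=U_perpS_half, span=span,
        chord_dir=chord_dir, vel_ref=vel_ref, acc_half=acc_half,
        degenerate=degenerate, chord=c_i, dr=dr, rho=frame.rho)


def element_state(frame: WingbeatFrame, side: str,
                  geom: BladeElementGeometry, tau: int,
                  wing_base_offset=None,
                  f_ref: float = 0.75) -> BladeElementState:
    """Scalar state of one element at phase sample ``tau`` (0..99)."""
    st = wing_states(frame, side, [geom], wing_base_offset, f_ref)
    return BladeElementState(
        U=float(st.U[tau, 0]), alpha=float(st.alpha[tau, 0]),
        U_parc=float(st.U_parc[tau, 0]), U_perpS=float(st.U_perpS[tau, 0]),
        u_par=st.u_par[tau, 0], u_perp=st.u_perp[tau, 0],
        u_norm=st.u_norm[tau, 0], a_norm=float(st.a_norm[tau, 0]),
        omega_pitch=float(st.omega_pitch[tau, 0]),
        U_perpS_half=float(st.U_perpS_half[tau, 0]), span=st.span[tau, 0],
        chord_dir=st.chord_dir[tau, 0],
        degenerate=bool(st.degenerate[tau, 0]))


# ---------------------------------------------------------------------------
# Force laws
# ---------------------------------------------------------------------------

def _check_positive(rho, chord, dr):
    if np.any(np.asarray(rho) <= 0):
        raise ValueError("air density must be positive")
    if np.any(np.asarray(chord) < 0) or np.any(np.asarray(dr) < 0):
        raise ValueError("chord and element width must be non-negative")


def quasi_steady_forces(states: ElementStates, coeffs: Coefficients):
    """Quasi-steady pressure lift and drag vectors, ``(n_phase, n, 3)``."""
    _check_positive(states.rho, states.chord, states.dr)
    pref = 0.5 * states.rho * states.U**2 * states.chord[None, :] * states.dr
    pref = np.where(states.degenerate, 0.0, pref)
    sin_a, cos_a = np.sin(states.alpha), np.cos(states.alpha)
    lift = (pref * coeffs.C_P_alpha * sin_a * cos_a)[..., None] * states.u_perp
    drag = (pref * (coeffs.C_P_alpha * sin_a**2 + coeffs.C_D0))[..., None] \
        * states.u_par
    return lift, drag


def added_mass_normal(states: ElementStates) -> np.ndarray:
    """Surface-normal added-mass force vectors, ``(n_phase, n, 3)``."""
    _check_positive(states.rho, states.chord, states.dr)
    mag = -(np.pi / 4.0) * states.rho * states.chord[None, :]**2 \
        * states.a_norm * states.dr
    return mag[..., None] * states.u_norm


def added_mass_parallel_oracle(states: ElementStates) -> np.ndarray:
    """Chordwise added-mass force (validation oracle, not summed into sums).

    The reaction to the rotating fluid momentum: ``-(pi/4) rho c^2 Omega_r
    U'_perpS (s x u_norm) dr``.  Together with :func:`added_mass_normal`
    this is the exact negative rate of change of the added fluid momentum,
    so the two integrate to zero over a strictly periodic planar cycle.
    """
    _check_positive(states.rho, states.chord, states.dr)
    sxn = np.cross(states.span, states.u_norm)
    mag = -(np.pi / 4.0) * states.rho * states.chord[None, :]**2 \
        * states.omega_pitch * states.U_perpS_half * states.dr
    return mag[..., None] * sxn


@dataclass
class StrokeSums:
    """Per-wingbeat summation vectors forming the regression design.

    ``C_Pa * sigma_P + C_D0 * sigma_D + sigma_A`` is the model's
    stroke-averaged force for the wing(s) summed over.
    """

    sigma_P: np.ndarray  # (3,)
    sigma_D: np.ndarray
    sigma_A: np.ndarray

    def __add__(self, other: "StrokeSums") -> "StrokeSums":
        return StrokeSums(self.sigma_P + other.sigma_P,
                          self.sigma_D + other.sigma_D,
                          self.sigma_A + other.sigma_A)


def stroke_sums(states: ElementStates) -> StrokeSums:
    """Stroke-averaged summation vectors for one wing.

    The lift and drag laws collapse, via the identity ``u_norm = u_perp cos a
    + u_par sin a``, into a part linear in C_Pa (along u_norm, weighted by
    sin a) and a part linear in C_D0 (along u_par), plus the added-mass sum.
    """
    pref = 0.5 * states.rho * states.U**2 * states.chord[None, :] * states.dr
    pref = np.where(states.degenerate, 0.0, pref)
    sin_a = np.sin(states.alpha)
    n_phase = states.U.shape[0]
    sigma_P = ((pref * sin_a)[..., None] * states.u_norm).sum((0, 1)) / n_phase
    sigma_D = (pref[..., None] * states.u_par).sum((0, 1)) / n_phase
    sigma_A = added_mass_normal(states).sum((0, 1)) / n_phase
    return StrokeSums(sigma_P, sigma_D, sigma_A)


def frame_stroke_sums(frame: WingbeatFrame,
                      planforms: dict[str, WingPlanform],
                      n_elements: int = 20,
                      f_ref: float = 0.75) -> dict[str, StrokeSums]:
    """Stroke sums per wing (keys 'left', 'right') plus combined 'LR'."""
    out = {}
    for side in ("left", "right"):
        pf = planforms[side]
        elements = discretize_planform(pf, n_elements)
        st = wing_states(frame, side, elements, pf.wing_base_offset, f_ref)
        out[side] = stroke_sums(st)
    out["LR"] = out["left"] + out["right"]
    return out


def predict_stroke_force(sums: StrokeSums, coeffs: Coefficients) -> np.ndarray:
    """Model stroke-averaged aerodynamic force; affine-linear in the coeffs."""
    return (coeffs.C_P_alpha * sums.sigma_P
            + coeffs.C_D0 * sums.sigma_D
            + sums.sigma_A)


def coefficient_curves(alpha, coeffs: Coefficients):
    """Lift/drag coefficients and resultant-force angle at incidence alpha.

    Returns ``(C_L, C_D, gamma)`` with ``gamma`` the angle of the resultant
    quasi-steady force from the chord line: ``gamma = alpha +
    arctan(C_L / C_D)``, which reaches 90 deg (force normal to the chord)
    only when the drag offset vanishes or the incidence is high.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < -1e-12) or np.any(alpha > np.pi / 2 + 1e-12):
        raise ValueError("alpha must lie in [0, pi/2]")
    C_L = coeffs.C_P_alpha * np.sin(alpha) * np.cos(alpha)
    C_D = coeffs.C_P_alpha * np.sin(alpha)**2 + coeffs.C_D0
    gamma = alpha + np.arctan2(C_L, C_D)
    return C_L, C_D, gamma
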