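"""Synthetic wingbeat kinematics with the structure the model assumes.

The generator emulates hovering-like periodic wingbeats of a hoverfly-scale
insect — roughly 188 Hz wingbeat frequency, an inclined near-sinusoidal tip
path (stroke and deviation angles of similar amplitude, in phase), and a
half-stroke-symmetric wing pitch profile built from a fundamental plus third
harmonic so that the mid-stroke angle of attack sits on a plateau near
30-50 degrees with rapid reversal — together with manoeuvring sequences in
which the body translates with non-zero stroke-averaged acceleration.

"Measured" stroke-averaged forces for parameter-recovery experiments are
forward-simulated from the model itself plus isotropic Gaussian noise, which
is exactly the generative structure the regression assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .bladeforces import Coefficients, frame_stroke_sums, predict_stroke_force
from .fitting import MeasuredForce, ProcessedWingbeat
from .kinematics import N_PHASE, RawSequence, WingbeatFrame
from .morphology import AirBody, WingPlanform, elliptical_planform
from .rotations import euler_zyx

__all__ = [
    "GeneratorParams",
    "SyntheticDataset",
    "default_planforms",
    "make_dataset",
    "analytic_frames",
    "frames_to_processed",
    "forward_simulate_measured",
    "calibrate_hover_amplitude",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic kinematics generator (SI units).

    The morphology defaults are plausible hoverfly-scale values: wing length
    9.5 mm, mean chord 3 mm, body mass 110 mg, air density 1.18 kg m^-3.
    ``stroke_amp`` is the half-amplitude of the stroke angle; the default is
    calibrated so that the standard coefficient values approximately support
    body weight in hover (see :func:`calibrate_hover_amplitude`).
    """

    wingbeat_freq: float = 188.0  # Hz
    stroke_amp: float = 1.02  # rad, half amplitude of phi
    deviation_ratio: float = 0.9  # theta amplitude as a fraction of stroke
    pitch_amp: float = 0.80  # rad, peak wing-pitch excursion
    pitch_mean: float = 0.72  # rad, chord follows the inclined tip path
    pitch_third: float = 1.0 / 3.0  # relative 3rd-harmonic content
    twist_grad_amp: float = 25.0  # rad / m, peak linear twist gradient
    body_pitch_deg: float = 43.6  # nose-up body attitude
    body_programme: str = "rest"  # rest | const_accel | saccade
    body_accel: tuple = (4.0, 1.0, 3.5)  # m s^-2 (const_accel / saccade peak)
    saccade_width: float = 0.02  # s, Gaussian width of the saccade pulse
    noise_sd: float = 0.0  # N, per-axis noise on forward-simulated forces
    wingbeat_jitter: float = 0.0  # slow within-sequence amplitude modulation
    n_sequences: int = 1
    wingbeats_per_sequence: int = 4
    amp_jitter: float = 0.0  # relative inter-sequence amplitude variability
    sample_rate: float = 3800.0  # Hz
    seed: int = 0
    # morphology
    wing_length: float = 9.5e-3
    mean_chord: float = 3.0e-3
    axis_fraction: float = 0.30
    mass: float = 110e-6
    rho: float = 1.18

    def __post_init__(self):
        if self.wingbeat_freq <= 0:
            raise ValueError("wingbeat frequency must be positive")
        for name in ("stroke_amp", "pitch_amp", "deviation_ratio",
                     "noise_sd", "amp_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.body_programme not in ("rest", "const_accel", "saccade"):
            raise ValueError(f"unknown body programme {self.body_programme!r}")

    @property
    def period(self) -> float:
        return 1.0 / self.wingbeat_freq

    def air(self) -> AirBody:
        return AirBody(mass=self.mass, rho=self.rho)


def default_planforms(params: GeneratorParams) -> dict[str, WingPlanform]:
    base = np.array([0.0, 1.2e-3, 0.5e-3])
    return {
        "right": elliptical_planform(params.wing_length, params.mean_chord,
                                     params.axis_fraction, side="right",
                                     wing_base_offset=base),
        "left": elliptical_planform(params.wing_length, params.mean_chord,
                                    params.axis_fraction, side="left",
                                    wing_base_offset=base * [1, -1, 1]),
    }


# ---------------------------------------------------------------------------
# Closed-form channel waveforms (value, 1st, 2nd derivative)
# ---------------------------------------------------------------------------

def _harmonic(t, freq, amp, harmonics):
    """Sum of a_k cos + b_k sin terms; returns (y, yd, ydd)."""
    w0 = 2.0 * np.pi * freq
    y = np.zeros_like(t)
    yd = np.zeros_like(t)
    ydd = np.zeros_like(t)
    for k, (a, b) in harmonics.items():
        w = k * w0
        c, s = np.cos(w * t), np.sin(w * t)
        y += amp * (a * c + b * s)
        yd += amp * w * (-a * s + b * c)
        ydd += amp * w**2 * (-a * c - b * s)
    return y, yd, ydd


def _pitch_wave(params: GeneratorParams):
    """Half-stroke-antisymmetric pitch waveform, normalized to unit peak."""
    x = np.linspace(0, 2 * np.pi, 2001)
    raw = np.sin(x) + params.pitch_third * np.sin(3 * x)
    peak = np.abs(raw).max()
    return {1: (0.0, 1.0 / peak), 3: (0.0, params.pitch_third / peak)}


def _envelope(t, mod):
    """Slow amplitude-modulation envelope (value, 1st, 2nd derivative)."""
    if mod is None:
        one = np.ones_like(t)
        return one, np.zeros_like(t), np.zeros_like(t)
    eps, f_mod, phase = mod
    w = 2.0 * np.pi * f_mod
    e = 1.0 + eps * np.sin(w * t + phase)
    return e, eps * w * np.cos(w * t + phase), \
        -eps * w**2 * np.sin(w * t + phase)


def _modulate(h, env):
    """Product-rule combination of a channel triple with an envelope."""
    e, ed, edd = env
    return (e * h[0], ed * h[0] + e * h[1],
            edd * h[0] + 2.0 * ed * h[1] + e * h[2])


def _wing_channels(t, params: GeneratorParams, amp_factor: float = 1.0,
                   mod=None):
    """Analytic stroke, deviation, pitch offset and twist gradient channels.

    The downstroke starts at t = 0 (stroke angle at its posterior extreme,
    about to decrease); stroke and deviation are in phase, giving a straight
    inclined tip path; pitch flips sign between half-strokes.  ``mod`` is an
    optional ``(eps, f_mod, phase)`` slow amplitude-modulation envelope on
    the stroke and deviation, emulating the wingbeat-to-wingbeat modulation
    that drives manoeuvres.
    """
    f = params.wingbeat_freq
    A = params.stroke_amp * amp_factor
    env = _envelope(t, mod)
    phi = _modulate(_harmonic(t, f, A, {1: (1.0, 0.0)}), env)
    theta = _modulate(
        _harmonic(t, f, A * params.deviation_ratio, {1: (1.0, 0.0)}), env)
    wave = _pitch_wave(params)
    om0 = _harmonic(t, f, -params.pitch_amp, wave)
    om0 = (om0[0] + params.pitch_mean, om0[1], om0[2])
    omr = _harmonic(t, f, params.twist_grad_amp, wave)
    return phi, theta, om0, omr


def _body_motion(t, params: GeneratorParams, accel_factor: float = 1.0):
    """Body position, velocity, acceleration per programme."""
    t = np.asarray(t, dtype=float)
    a_vec = np.asarray(params.body_accel, dtype=float) * accel_factor
    if params.body_programme == "rest":
        z = np.zeros(t.shape + (3,))
        return z, z.copy(), z.copy()
    if params.body_programme == "const_accel":
        pos = 0.5 * np.outer(t**2, a_vec)
        vel = np.outer(t, a_vec)
        acc = np.broadcast_to(a_vec, t.shape + (3,)).copy()
        return pos, vel, acc
    # saccade: Gaussian acceleration pulse centred mid-sequence
    sig = params.saccade_width
    tc = t.mean()
    u = (t - tc) / (np.sqrt(2.0) * sig)
    u0 = (t[0] - tc) / (np.sqrt(2.0) * sig)
    amp = np.sqrt(np.pi / 2.0) * sig
    vel_s = amp * (erf(u) - erf(u0))

    def F(x):
        return x * erf(x) + np.exp(-(x**2)) / np.sqrt(np.pi)

    pos_s = amp * np.sqrt(2.0) * sig * (F(u) - F(u0)) \
        - amp * erf(u0) * (t - t[0])
    acc_s = np.exp(-((t - tc) ** 2) / (2.0 * sig**2))
    return (np.outer(pos_s, a_vec), np.outer(vel_s, a_vec),
            np.outer(acc_s, a_vec))


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Raw synthetic sequences plus the ground-truth generation record."""

    sequences: list[RawSequence]
    params: GeneratorParams
    truth: dict


def make_dataset(params: GeneratorParams) -> SyntheticDataset:
    """Generate raw kinematic sequences sampled at the nominal camera rate.

    Each sequence covers ``wingbeats_per_sequence`` full wingbeats plus half
    a wingbeat of margin on either side so that segmentation can find the
    bounding half-stroke reversals.  The local pitch angle is emitted at six
    spanwise stations, consistent with the linear twist model, so the full
    twist-regression path is exercised downstream.
    """
    rng = np.random.default_rng(params.seed)
    T = params.period
    sequences = []
    truth = {"amp_factors": [], "accel_factors": [], "seed": params.seed}
    stations = np.linspace(0.1, 0.95, 6) * params.wing_length
    for s in range(params.n_sequences):
        amp_f = 1.0 + params.amp_jitter * rng.standard_normal()
        acc_f = float(rng.uniform(-1.0, 1.0)) if params.n_sequences > 1 \
            else 1.0
        truth["amp_factors"].append(amp_f)
        truth["accel_factors"].append(acc_f)
        t0, t1 = -0.6 * T, (params.wingbeats_per_sequence + 0.6) * T
        n = int(np.ceil((t1 - t0) * params.sample_rate))
        t = t0 + np.arange(n) / params.sample_rate
        mod = None
        if params.wingbeat_jitter > 0:
            mod = (params.wingbeat_jitter,
                   float(rng.uniform(0.10, 0.25)) * params.wingbeat_freq,
                   float(rng.uniform(0, 2 * np.pi)))
        phi, theta, om0, omr = _wing_channels(t, params, amp_f, mod)
        pos, _, _ = _body_motion(t, params, acc_f)
        euler = np.zeros((n, 3))
        euler[:, 1] = -np.deg2rad(params.body_pitch_deg)
        wings = {}
        for side in ("left", "right"):
            omega_samples = om0[0][:, None] + omr[0][:, None] * stations
            wings[side] = {"phi": phi[0].copy(), "theta": theta[0].copy(),
                           "omega_samples": omega_samples,
                           "omega_stations": stations.copy()}
        sequences.append(RawSequence(
            t=t - t0, body_position=pos, body_euler=euler, wings=wings,
            insect_id="synthetic", sequence_id=f"seq{s:03d}",
            mass=params.mass, rho=params.rho))
    return SyntheticDataset(sequences=sequences, params=params, truth=truth)


def analytic_frames(params: GeneratorParams,
                    amp_factor: float = 1.0,
                    accel_factor: float = 1.0,
                    n_wingbeats: int | None = None,
                    sequence_id: str = "seq000",
                    mod=None) -> list[WingbeatFrame]:
    """Wingbeat frames evaluated directly from the closed-form waveforms.

    Bypasses smoothing and segmentation: channel values and their first two
    derivatives are exact, which makes these frames the reference input for
    force-law, convergence and recovery tests.  ``mod`` is the optional
    ``(eps, f_mod, phase)`` amplitude-modulation envelope.
    """
    T = params.period
    n_wb = n_wingbeats or params.wingbeats_per_sequence
    frames = []
    for k in range(n_wb):
        t = k * T + np.arange(N_PHASE) / N_PHASE * T
        phi, theta, om0, omr = _wing_channels(t, params, amp_factor, mod)
        pos, vel, acc = _body_motion(t, params, accel_factor)
        euler = np.zeros((N_PHASE, 3))
        euler[:, 1] = -np.deg2rad(params.body_pitch_deg)
        wing = {"phi": phi[0], "phi_d": phi[1], "phi_dd": phi[2],
                "theta": theta[0], "theta_d": theta[1], "theta_dd": theta[2],
                "omega0": om0[0], "omega0_d": om0[1], "omega0_dd": om0[2],
                "omega_r": omr[0], "omega_r_d": omr[1], "omega_r_dd": omr[2]}
        frames.append(WingbeatFrame(
            n=k, t=t, period=T, body_pos=pos, body_vel=vel, body_acc=acc,
            euler=euler, euler_d=np.zeros((N_PHASE, 3)),
            euler_dd=np.zeros((N_PHASE, 3)),
            wings={"left": dict(wing), "right": dict(wing)},
            mass=params.mass, rho=params.rho, sequence_id=sequence_id))
    return frames


def frames_to_processed(frames: list[WingbeatFrame],
                        planforms: dict[str, WingPlanform],
                        f_ref: float = 0.75,
                        n_elements: int = 20) -> list[ProcessedWingbeat]:
    """Wrap frames with their stroke sums and a placeholder measurement."""
    out = []
    for fr in frames:
        sums = frame_stroke_sums(fr, planforms, n_elements, f_ref)
        R = euler_zyx(*fr.euler.mean(axis=0))
        meas = MeasuredForce(n=fr.n, F_lab=np.zeros(3), R_body=R)
        out.append(ProcessedWingbeat(frame=fr, planforms=planforms,
                                     measured=meas, sums=sums,
                                     sequence_id=fr.sequence_id))
    return out


def forward_simulate_measured(dataset: list[ProcessedWingbeat],
                              true_coeffs: Coefficients,
                              noise_sd: float = 0.0,
                              seed: int = 0) -> list[ProcessedWingbeat]:
    """Attach model-generated measured forces: prediction plus Gaussian noise.

    This realizes the regression's generative model exactly, so that fitting
    the simulated dataset with zero noise recovers ``true_coeffs`` to
    numerical precision.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for wb in dataset:
        F = predict_stroke_force(wb.sums["LR"], true_coeffs)
        if noise_sd > 0:
            F = F + noise_sd * rng.standard_normal(3)
        meas = MeasuredForce(n=wb.measured.n, F_lab=F,
                             R_body=wb.measured.R_body)
        out.append(replace(wb, measured=meas))
    return out


def calibrate_hover_amplitude(params: GeneratorParams,
                              coeffs: Coefficients,
                              planforms: dict[str, WingPlanform] | None = None,
                              lo: float = 0.5, hi: float = 1.5
                              ) -> GeneratorParams:
    """Scale the stroke amplitude so the model supports body weight in hover.

    Solves, by bisection on the amplitude factor, for a zero of the vertical
    force balance ``F_z(amp) - m g`` of a single rest-programme wingbeat
    under the supplied coefficients.
    """
    if planforms is None:
        planforms = default_planforms(params)
    rest = replace(params, body_programme="rest")
    weight = rest.air().weight

    def imbalance(factor):
        frame = analytic_frames(rest, amp_factor=factor, n_wingbeats=1)[0]
        sums = frame_stroke_sums(frame, planforms, f_ref=coeffs.f_ref)
        return predict_stroke_force(sums["LR"], coeffs)[2] - weight

    factor = brentq(imbalance, lo, hi, xtol=1e-10)
    return replace(params, stroke_amp=params.stroke_amp * factor)
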