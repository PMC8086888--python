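"""Kinematic time-series processing for flapping-flight analysis.

Raw wing and body kinematics are smoothed with quintic smoothing splines whose
residual tolerance is tied, for transparency, to the variation that a
zero-phase third-order Butterworth filter would remove at a stated cut-off
frequency.  The smoothed signals are differentiated analytically, split into
wingbeats at minima of the mean wing-tip angular speed, resampled at 100
evenly spaced phases per wingbeat starting at the downstroke, and optionally
compressed into a truncated Fourier series plus cubic polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import spsolve

__all__ = [
    "RawSequence",
    "KinematicChannel",
    "SequenceChannels",
    "WingbeatFrame",
    "Segmentation",
    "HarmonicSeries",
    "TwistFit",
    "SmoothingConfig",
    "smooth_channel",
    "smooth_sequence",
    "segment_wingbeats",
    "resample_wingbeat",
    "fit_harmonics",
    "fit_linear_twist",
]

N_PHASE = 100  # samples per wingbeat after resampling

WING_KEYS = ("phi", "theta", "omega0", "omega_r")


@dataclass(frozen=True)
class SmoothingConfig:
    """Butterworth-equivalent cut-off frequencies (Hz) per signal class."""

    body_hz: float = 100.0
    tip_hz: float = 500.0
    twist_hz: float = 800.0


@dataclass
class RawSequence:
    """One flight sequence of raw kinematic samples.

    ``t`` must be strictly increasing (nominally 3800 Hz).  Body orientation
    is carried as intrinsic Z-Y'-X'' (yaw-pitch-roll) Euler angles in
    radians; wing angles are the stroke angle ``phi`` and deviation angle
    ``theta`` of each wing tip, plus the local pitch angle sampled at several
    spanwise stations (``omega_samples`` with shape ``(n_samples,
    n_stations)``) or pre-fitted ``omega0``/``omega_r`` series.
    """

    t: np.ndarray
    body_position: np.ndarray  # (N, 3) metres, lab frame, Z vertical
    body_euler: np.ndarray  # (N, 3) rad, (yaw, pitch, roll)
    wings: dict  # side -> {"phi","theta"} and either omega samples or fits
    insect_id: str = "synthetic"
    sequence_id: str = "seq0"
    mass: float | None = None  # kg
    rho: float = 1.18  # kg m^-3

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("t must be a 1-D array with >= 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        self.body_position = np.asarray(self.body_position, dtype=float)
        self.body_euler = np.asarray(self.body_euler, dtype=float)
        for arr in (self.body_position, self.body_euler):
            if arr.shape != (len(self.t), 3):
                raise ValueError("body arrays must have shape (n_samples, 3)")
        for side in ("left", "right"):
            if side not in self.wings:
                raise ValueError(f"missing wing data for side {side!r}")

    def twist_series(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample (omega0, omega_r) from spanwise pitch samples.

        If the wing dict already carries fitted ``omega0``/``omega_r`` series
        these are returned directly; otherwise the linear twist model is
        regressed on the spanwise stations independently at every time sample.
        """
        w = self.wings[side]
        if "omega0" in w and "omega_r" in w:
            return (np.asarray(w["omega0"], float),
                    np.asarray(w["omega_r"], float))
        stations = np.asarray(w["omega_stations"], dtype=float)
        samples = np.asarray(w["omega_samples"], dtype=float)
        design = np.column_stack([np.ones_like(stations), stations])
        coef, *_ = np.linalg.lstsq(design, samples.T, rcond=None)
        return coef[0], coef[1]


# ---------------------------------------------------------------------------
# Quintic smoothing spline with Butterworth-matched tolerance
# ---------------------------------------------------------------------------

def _deriv_operator(knots: np.ndarray, k: int) -> sparse.csr_matrix:
    """Sparse operator mapping spline coefficients to derivative coefficients.

    For a spline of degree ``k`` on knot vector ``knots`` with ``n``
    coefficients, the derivative is a degree ``k-1`` spline with ``n-1``
    coefficients ``k (c[i+1]-c[i]) / (knots[i+k+1]-knots[i+1])``.
    """
    n = len(knots) - k - 1
    gaps = knots[1 + k:n + k] - knots[1:n]
    with np.errstate(divide="ignore"):
        scale = np.where(gaps > 0, k / np.where(gaps > 0, gaps, 1.0), 0.0)
    rows = np.repeat(np.arange(n - 1), 2)
    cols = np.column_stack([np.arange(n - 1), np.arange(1, n)]).ravel()
    vals = np.column_stack([-scale, scale]).ravel()
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n - 1, n))


def _penalty_matrix(knots: np.ndarray, k: int, order: int = 3):
    """Gram matrix of order-th derivatives: P = L^T G L.

    ``G`` is the Gram matrix of the degree ``k-order`` basis, computed
    exactly with Gauss-Legendre quadrature on each knot interval.
    """
    L = sparse.eye(len(knots) - k - 1, format="csr")
    kk, t = k, knots
    for _ in range(order):
        D = _deriv_operator(t, kk)
        L = D @ L
        t = t[1:-1]
        kk -= 1
    # quadrature nodes on each non-degenerate interval of the derived knots
    interior = np.unique(t)
    a, b = interior[:-1], interior[1:]
    q, w = np.polynomial.legendre.leggauss(max(kk + 1, 2))
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    x = (mid[:, None] + half[:, None] * q[None, :]).ravel()
    wts = (half[:, None] * w[None, :]).ravel()
    B = BSpline.design_matrix(x, t, kk, extrapolate=False)
    G = (B.T.multiply(wts)) @ B
    return (L.T @ G @ L).tocsc()


@dataclass
class KinematicChannel:
    """A smoothed kinematic signal with analytic derivatives.

    Wraps a quintic spline whose residual sum of squares against the raw
    samples equals the Butterworth-removed tolerance (see
    :func:`smooth_channel`).
    """

    spline: BSpline
    cutoff_hz: float
    tolerance: float
    achieved_ss: float
    domain: tuple[float, float]

    def __call__(self, t, nu: int = 0) -> np.ndarray:
        return self.spline(t, nu=nu)

    def derivative(self, nu: int = 1) -> BSpline:
        return self.spline.derivative(nu)


def _fit_penalized(BtB, Bty, P, lam):
    c = spsolve((BtB + lam * P).tocsc(), Bty)
    return np.asarray(c)


def smooth_channel(t, y, cutoff_hz: float) -> KinematicChannel:
    """Quintic smoothing spline with a Butterworth-equivalent tolerance.

    The spline's residual sum of squares is made equal (to ~1e-6 relative, by
    bisection on the roughness penalty) to the sum of squared variation that a
    zero-phase (forward-backward) third-order Butterworth filter with cut-off
    ``cutoff_hz`` would have removed from the raw signal.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("t and y must be 1-D arrays of equal length")
    n = len(t)
    if n < 20:
        raise ValueError(f"need >= 20 samples to smooth, got {n}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("t must be strictly increasing")
    fs = 1.0 / np.median(dt)
    if cutoff_hz >= fs / 2.0 * (1.0 - 1e-9):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({fs / 2:.1f} Hz)")

    # zero-phase Butterworth; the long odd-reflection pad reaches the
    # steady-state response so band-limited signals yield a ~zero tolerance
    sos = sps.butter(3, cutoff_hz, fs=fs, output="sos")
    padlen = min(n - 1, 10 * int(fs / cutoff_hz) + 21)
    y_filt = sps.sosfiltfilt(sos, y, padlen=padlen)
    tol = float(np.sum((y - y_filt) ** 2))

    # B-spline basis with knots at the data sites (classical smoothing spline)
    k = 5
    knots = np.concatenate([np.full(k + 1, t[0]), t[1:-1],
                            np.full(k + 1, t[-1])])
    B = BSpline.design_matrix(t, knots, k, extrapolate=False)
    BtB = (B.T @ B).tocsc()
    Bty = B.T @ y
    P = _penalty_matrix(knots, k, order=3)

    scale_ss = float(np.sum((y - y.mean()) ** 2))
    lam_scale = BtB.diagonal().sum() / max(P.diagonal().sum(), 1e-300)
    # roundoff floor: constant or band-limited signals get an (effectively)
    # interpolating spline rather than a penalty bisection
    tiny = max(scale_ss * 1e-11,
               n * (1e-12 * max(1.0, float(np.abs(y).max()))) ** 2)
    if tol <= tiny:
        # signal is entirely below the cut-off: interpolate exactly
        from scipy.interpolate import make_interp_spline
        spl = make_interp_spline(t, y, k=k)
        ach = float(np.sum((y - spl(t)) ** 2))
        return KinematicChannel(spl, cutoff_hz, tol, ach, (t[0], t[-1]))

    # bracket the penalty so that SS(lam_lo) < tol < SS(lam_hi)
    def resid_ss(lam):
        c = _fit_penalized(BtB, Bty, P, lam)
        return float(np.sum((y - B @ c) ** 2)), c

    lo, hi = lam_scale * 1e-14, lam_scale * 1e6
    ss_lo, _ = resid_ss(lo)
    ss_hi, _ = resid_ss(hi)
    it = 0
    while ss_lo > tol and it < 20:
        lo /= 100.0
        ss_lo, _ = resid_ss(lo)
        it += 1
    it = 0
    while ss_hi < tol and it < 20:
        hi *= 100.0
        ss_hi, _ = resid_ss(hi)
        it += 1
    if ss_lo > tol or ss_hi < tol:
        raise RuntimeError("failed to bracket the smoothing penalty")
    # bisection in log-lambda until the residual matches the tolerance
    for _ in range(100):
        mid = np.sqrt(lo * hi)
        ss_mid, c_mid = resid_ss(mid)
        if abs(ss_mid - tol) <= 1e-7 * tol:
            break
        if ss_mid < tol:
            lo = mid
        else:
            hi = mid
    spl = BSpline(knots, c_mid, k)
    ach = float(np.sum((y - spl(t)) ** 2))
    return KinematicChannel(spl, cutoff_hz, tol, ach, (t[0], t[-1]))


@dataclass
class SequenceChannels:
    """Smoothed channels for one flight sequence."""

    body_position: list  # 3 KinematicChannel (X, Y, Z)
    body_euler: list  # 3 KinematicChannel (yaw, pitch, roll)
    wings: dict  # side -> {key: KinematicChannel} for WING_KEYS
    mass: float | None = None
    rho: float = 1.18
    sequence_id: str = "seq0"
    insect_id: str = "synthetic"

    @property
    def domain(self) -> tuple[float, float]:
        lows, highs = [], []
        for ch in self._all_channels():
            lows.append(ch.domain[0])
            highs.append(ch.domain[1])
        return max(lows), min(highs)

    def _all_channels(self):
        yield from self.body_position
        yield from self.body_euler
        for w in self.wings.values():
            yield from w.values()


def smooth_sequence(raw: RawSequence,
                    config: SmoothingConfig = SmoothingConfig()
                    ) -> SequenceChannels:
    """Smooth every channel of a raw sequence at its class cut-off."""
    body_pos = [smooth_channel(raw.t, raw.body_position[:, i], config.body_hz)
                for i in range(3)]
    body_eul = [smooth_channel(raw.t, raw.body_euler[:, i], config.body_hz)
                for i in range(3)]
    wings = {}
    for side in ("left", "right"):
        w = raw.wings[side]
        omega0, omega_r = raw.twist_series(side)
        wings[side] = {
            "phi": smooth_channel(raw.t, np.asarray(w["phi"], float),
                                  config.tip_hz),
            "theta": smooth_channel(raw.t, np.asarray(w["theta"], float),
                                    config.tip_hz),
            "omega0": smooth_channel(raw.t, omega0, config.twist_hz),
            "omega_r": smooth_channel(raw.t, omega_r, config.twist_hz),
        }
    return SequenceChannels(body_pos, body_eul, wings, mass=raw.mass,
                            rho=raw.rho, sequence_id=raw.sequence_id,
                            insect_id=raw.insect_id)


# ---------------------------------------------------------------------------
# Wingbeat segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segmentation:
    """Half-stroke boundaries and the wingbeats assembled from them."""

    boundaries: np.ndarray  # times of tip-speed minima
    is_downstroke: np.ndarray  # flag per interval (boundary i -> i+1)
    wingbeats: list  # list of (start, end) covering one full wingbeat each


def _tip_speed(channels: SequenceChannels, t):
    """Mean over the two wings of the tip angular speed.

    The tip angular speed is the great-circle rate of the wing-base to
    wing-tip direction, ``sqrt(phidot^2 cos^2 theta + thetadot^2)``.
    """
    total = 0.0
    for side in ("left", "right"):
        w = channels.wings[side]
        phi_d = w["phi"](t, nu=1)
        th = w["theta"](t)
        th_d = w["theta"](t, nu=1)
        total = total + np.sqrt(phi_d**2 * np.cos(th)**2 + th_d**2)
    return total / 2.0


def segment_wingbeats(channels: SequenceChannels,
                      downstroke_sign: float = -1.0,
                      oversample: int = 16) -> Segmentation:
    """Split smoothed kinematics into wingbeats.

    Half-stroke boundaries are the local minima of the mean tip angular speed
    of the two wings.  A full wingbeat runs from one downstroke start to the
    next; the downstroke is identified (by default) as the half-stroke on
    which the right wing's stroke angle decreases, a configurable sign
    convention.
    """
    t0, t1 = channels.domain
    if t1 <= t0:
        raise ValueError("channels have no common time interval")
    # dense evaluation grid
    knots = channels.wings["right"]["phi"].spline.t
    step = np.median(np.diff(np.unique(knots))) / oversample
    tt = np.arange(t0, t1, step)
    v = _tip_speed(channels, tt)
    idx = sps.argrelmin(v, order=2)[0]
    idx = idx[(idx > 0) & (idx < len(tt) - 1)]
    if len(idx) < 2:
        raise ValueError(
            "fewer than two tip-speed minima: interval shorter than one "
            "wingbeat period")
    # refine each minimum within its bracket
    mins = []
    for i in idx:
        res = minimize_scalar(lambda x: _tip_speed(channels, x),
                              bounds=(tt[i - 1], tt[i + 1]), method="bounded",
                              options={"xatol": step * 1e-6})
        mins.append(res.x)
    mins = np.array(mins)

    # tie-break shallow double minima: merge boundaries much closer than the
    # typical half-stroke and keep the one closest to a reversal of the mean
    # stroke rate (|mean phidot| smallest)
    spacing = np.median(np.diff(mins))
    merged = []
    group = [mins[0]]
    for m in mins[1:]:
        if m - group[-1] < 0.25 * spacing:
            group.append(m)
        else:
            merged.append(_pick_boundary(channels, group))
            group = [m]
    merged.append(_pick_boundary(channels, group))
    boundaries = np.array(merged)

    # classify each inter-boundary interval
    mid = (boundaries[:-1] + boundaries[1:]) / 2.0
    phi_rate = (channels.wings["right"]["phi"](mid, nu=1) +
                channels.wings["left"]["phi"](mid, nu=1)) / 2.0
    is_down = np.sign(phi_rate) == np.sign(downstroke_sign)

    wingbeats = []
    i = 0
    while i + 2 <= len(boundaries) - 1:
        if is_down[i]:
            wingbeats.append((float(boundaries[i]), float(boundaries[i + 2])))
            i += 2
        else:
            i += 1
    return Segmentation(boundaries, is_down, wingbeats)


def _pick_boundary(channels, group):
    if len(group) == 1:
        return group[0]
    rate = [abs(channels.wings["right"]["phi"](g, nu=1) +
                channels.wings["left"]["phi"](g, nu=1)) for g in group]
    return group[int(np.argmin(rate))]


# ---------------------------------------------------------------------------
# Resampling into wingbeat frames
# ---------------------------------------------------------------------------

@dataclass
class WingbeatFrame:
    """One wingbeat sampled at 100 evenly spaced phases from downstroke start.

    Carries the body's lab-frame position/orientation and the per-wing angle
    channels together with their first and second analytic time derivatives.
    """

    n: int
    t: np.ndarray  # (100,) absolute times
    period: float
    body_pos: np.ndarray  # (100, 3)
    body_vel: np.ndarray
    body_acc: np.ndarray
    euler: np.ndarray  # (100, 3) yaw, pitch, roll
    euler_d: np.ndarray
    euler_dd: np.ndarray
    wings: dict  # side -> {key, key+"_d", key+"_dd": (100,)}
    mass: float | None = None
    rho: float = 1.18
    sequence_id: str = "seq0"
    insect_id: str = "synthetic"

    @property
    def phase(self) -> np.ndarray:
        return np.arange(N_PHASE) / N_PHASE

    def mean_body_acc(self) -> np.ndarray:
        return self.body_acc.mean(axis=0)

    def mean_body_speed(self) -> float:
        return float(np.linalg.norm(self.body_vel, axis=1).mean())


def resample_wingbeat(channels: SequenceChannels,
                      interval: tuple[float, float],
                      n: int = 0) -> WingbeatFrame:
    """Resample smoothed channels at 100 evenly spaced phases of a wingbeat.

    Values and first/second derivatives are evaluated analytically from the
    smoothing splines at ``t_j = start + j T / 100``; the endpoint (phase 1)
    is the start of the next wingbeat and is not duplicated.
    """
    start, end = interval
    if end <= start:
        raise ValueError("wingbeat interval must have end > start")
    lo, hi = channels.domain
    if start < lo - 1e-12 or end > hi + 1e-12:
        raise ValueError("wingbeat interval lies outside the smoothed domain")
    period = end - start
    t = start + np.arange(N_PHASE) / N_PHASE * period

    def ev(ch_list):
        return (np.stack([c(t) for c in ch_list], axis=1),
                np.stack([c(t, nu=1) for c in ch_list], axis=1),
                np.stack([c(t, nu=2) for c in ch_list], axis=1))

    pos, vel, acc = ev(channels.body_position)
    eul, eul_d, eul_dd = ev(channels.body_euler)
    wings = {}
    for side, chans in channels.wings.items():
        d = {}
        for key in WING_KEYS:
            d[key] = chans[key](t)
            d[key + "_d"] = chans[key](t, nu=1)
            d[key + "_dd"] = chans[key](t, nu=2)
        wings[side] = d
    return WingbeatFrame(n=n, t=t, period=period, body_pos=pos, body_vel=vel,
                         body_acc=acc, euler=eul, euler_d=eul_d,
                         euler_dd=eul_dd, wings=wings, mass=channels.mass,
                         rho=channels.rho, sequence_id=channels.sequence_id,
                         insect_id=channels.insect_id)


# ---------------------------------------------------------------------------
# Harmonic compression
# ---------------------------------------------------------------------------

@dataclass
class HarmonicSeries:
    """Truncated Fourier series plus cubic polynomial for one channel.

    The polynomial is expressed in normalized time ``tau = t / period`` from
    the wingbeat start; Fourier terms are at multiples of the wingbeat
    fundamental.  Evaluation and derivatives are analytic.
    """

    period: float
    order: int
    poly: np.ndarray  # (4,) coefficients of 1, tau, tau^2, tau^3
    cos_coeffs: np.ndarray  # (order,)
    sin_coeffs: np.ndarray
    captured_variance: float = 1.0

    @property
    def fundamental(self) -> float:
        return 1.0 / self.period

    def evaluate(self, t, nu: int = 0) -> np.ndarray:
        """Evaluate (or differentiate) at times ``t`` from wingbeat start."""
        t = np.asarray(t, dtype=float)
        tau = t / self.period
        out = np.zeros_like(tau)
        # polynomial part, d^nu/dt^nu of sum a_m tau^m
        for m in range(4):
            if m - nu >= 0:
                fac = np.prod(np.arange(m - nu + 1, m + 1), dtype=float)
                out += self.poly[m] * fac * tau**(m - nu) / self.period**nu
        k = np.arange(1, self.order + 1)
        wk = 2.0 * np.pi * k / self.period  # angular frequency per harmonic
        arg = np.outer(tau * self.period, wk)
        cos_t, sin_t = np.cos(arg), np.sin(arg)
        a, b = self.cos_coeffs, self.sin_coeffs
        if nu % 4 == 0:
            ca, cb = a, b
            basis_a, basis_b = cos_t, sin_t
        elif nu % 4 == 1:
            ca, cb = -a, b
            basis_a, basis_b = sin_t, cos_t
        elif nu % 4 == 2:
            ca, cb = -a, -b
            basis_a, basis_b = cos_t, sin_t
        else:
            ca, cb = a, -b
            basis_a, basis_b = sin_t, cos_t
        out += basis_a @ (ca * wk**nu) + basis_b @ (cb * wk**nu)
        return out


def fit_harmonics(values, period: float, order: int) -> HarmonicSeries:
    """Least-squares harmonic fit of a 100-sample wingbeat channel.

    The basis is a cubic polynomial in time from wingbeat start plus cosine
    and sine terms of orders ``1..order`` at the wingbeat fundamental.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) != N_PHASE:
        raise ValueError(f"expected {N_PHASE} samples, got {y.shape}")
    if order < 1:
        raise ValueError("order must be >= 1")
    tau = np.arange(N_PHASE) / N_PHASE
    k = np.arange(1, order + 1)
    arg = 2.0 * np.pi * np.outer(tau, k)
    X = np.column_stack([np.ones_like(tau), tau, tau**2, tau**3,
                         np.cos(arg), np.sin(arg)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"harmonic order {order} gives a rank-deficient "
                         "design on 100 samples")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    captured = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return HarmonicSeries(period=period, order=order, poly=coef[:4],
                          cos_coeffs=coef[4:4 + order],
                          sin_coeffs=coef[4 + order:],
                          captured_variance=captured)


# ---------------------------------------------------------------------------
# Linear twist fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwistFit:
    """Linear spanwise twist model: pitch offset and twist gradient."""

    omega0: float  # rad
    omega_r: float  # rad / m


def fit_linear_twist(r, omega) -> TwistFit:
    """Ordinary least squares of local pitch angle on spanwise position."""
    r = np.asarray(r, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if r.shape != omega.shape or r.ndim != 1:
        raise ValueError("r and omega must be 1-D arrays of equal length")
    if len(np.unique(r)) < 2:
        raise ValueError("need >= 2 distinct spanwise stations")
    slope, intercept = np.polyfit(r, omega, 1)
    return TwistFit(omega0=float(intercept), omega_r=float(slope))
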