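"""Standard hovering wingbeat: selection, averaging and force decomposition.

Near-hover wingbeats are those whose stroke-averaged body acceleration stays
strictly below a threshold (default 0.5 m s^-2) in both the vertical and the
horizontal, from which the slowest quantile (default 1%) is averaged phase by
phase into a single reference wingbeat.  The average is refitted with the
harmonic basis and its cubic polynomial terms are zeroed, making the
reference strictly periodic; the body is held stationary at the subset's
mean pitch attitude with zero roll.  The time-varying model force for this
reference wingbeat is then decomposed into lift, drag and added-mass
contributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bladeforces import (Coefficients, added_mass_normal,
                          quasi_steady_forces, wing_states)
from .fitting import ProcessedWingbeat
from .kinematics import (N_PHASE, HarmonicSeries, WingbeatFrame,
                         fit_harmonics)
from .morphology import WingPlanform, discretize_planform
from .rotations import euler_zyx

__all__ = [
    "HoverCriteria",
    "StandardWingbeat",
    "select_hover_wingbeats",
    "build_standard_wingbeat",
    "decompose_time_forces",
]

HARMONIC_ORDERS = {"phi": 4, "theta": 4, "omega0": 6, "omega_r": 6}


@dataclass(frozen=True)
class HoverCriteria:
    """Thresholds defining near-equilibrium flight."""

    max_accel: float = 0.5  # m s^-2, strict bound, vertical and horizontal
    speed_quantile: float = 0.01  # fraction of all wingbeats kept

    def __post_init__(self):
        if self.max_accel <= 0:
            raise ValueError("max_accel must be positive")
        if not 0.0 < self.speed_quantile <= 1.0:
            raise ValueError("speed_quantile must lie in (0, 1]")


def select_hover_wingbeats(dataset: list[ProcessedWingbeat],
                           criteria: HoverCriteria = HoverCriteria()
                           ) -> list[ProcessedWingbeat]:
    """Filter to near-equilibrium wingbeats, then keep the slowest quantile.

    The acceleration criterion is applied with strict inequality separately
    to the vertical component and to the horizontal magnitude of the
    stroke-averaged body acceleration; ties at the speed-quantile boundary
    are broken by lower speed, then lower wingbeat index.
    """
    candidates = []
    for idx, wb in enumerate(dataset):
        acc = wb.frame.mean_body_acc()
        vertical = abs(acc[2])
        horizontal = float(np.hypot(acc[0], acc[1]))
        if vertical < criteria.max_accel and horizontal < criteria.max_accel:
            candidates.append((wb.frame.mean_body_speed(), idx, wb))
    if not candidates:
        raise ValueError("no wingbeats satisfy the hover acceleration "
                         "criterion")
    n_keep = max(1, math.ceil(criteria.speed_quantile * len(dataset)))
    candidates.sort(key=lambda c: (c[0], c[1]))
    return [wb for _, _, wb in candidates[:n_keep]]


@dataclass
class StandardWingbeat:
    """Strictly periodic reference wingbeat with a stationary body."""

    period: float
    body_pitch_deg: float  # nose-up attitude of the body's long axis
    harmonics: dict  # side -> {channel: HarmonicSeries}
    mass: float
    rho: float

    def frame(self, n_samples: int = N_PHASE) -> WingbeatFrame:
        """Evaluate the harmonics into an ``n_samples``-phase wingbeat frame."""
        t = np.arange(n_samples) / n_samples * self.period
        euler = np.zeros((n_samples, 3))
        euler[:, 1] = -np.deg2rad(self.body_pitch_deg)
        z3 = np.zeros((n_samples, 3))
        wings = {}
        for side, chans in self.harmonics.items():
            d = {}
            for key, series in chans.items():
                d[key] = series.evaluate(t)
                d[key + "_d"] = series.evaluate(t, nu=1)
                d[key + "_dd"] = series.evaluate(t, nu=2)
            wings[side] = d
        return WingbeatFrame(n=0, t=t, period=self.period, body_pos=z3,
                             body_vel=z3.copy(), body_acc=z3.copy(),
                             euler=euler, euler_d=z3.copy(),
                             euler_dd=z3.copy(), wings=wings, mass=self.mass,
                             rho=self.rho, sequence_id="standard")

    @property
    def is_periodic(self) -> bool:
        return all(np.allclose(s.poly[1:], 0.0)
                   for chans in self.harmonics.values()
                   for s in chans.values())


def build_standard_wingbeat(subset: list[ProcessedWingbeat]
                            ) -> StandardWingbeat:
    """Average the selected wingbeats at matched phase and make it periodic."""
    if len(subset) < 2:
        raise ValueError("need >= 2 wingbeats to build a standard wingbeat")
    keys = set(subset[0].frame.wings["right"])
    for wb in subset:
        if set(wb.frame.wings["right"]) != keys:
            raise ValueError("inconsistent channel sets across wingbeats")
    period = float(np.mean([wb.frame.period for wb in subset]))
    pitch_deg = float(np.rad2deg(
        -np.mean([wb.frame.euler[:, 1].mean() for wb in subset])))
    mass = subset[0].frame.mass
    rho = subset[0].frame.rho
    harmonics = {}
    for side in ("left", "right"):
        chans = {}
        for key, order in HARMONIC_ORDERS.items():
            mean_curve = np.mean(
                [wb.frame.wings[side][key] for wb in subset], axis=0)
            series = fit_harmonics(mean_curve, period, order)
            series.poly[1:] = 0.0  # strictly periodic
            chans[key] = series
        harmonics[side] = chans
    return StandardWingbeat(period=period, body_pitch_deg=pitch_deg,
                            harmonics=harmonics, mass=mass, rho=rho)


@dataclass
class ForceDecomposition:
    """Per-phase force components for one wing plus vertical-share summary."""

    phase: np.ndarray  # (100,)
    lift: dict  # side -> (100, 3) lab-frame vectors
    drag: dict
    added_mass: dict
    total: dict
    lift_body: dict  # side -> (100, 3) body-frame vectors
    drag_body: dict
    added_mass_body: dict
    vertical_share: dict  # {"lift", "added_mass", "drag"} percentages


def decompose_time_forces(std: StandardWingbeat,
                          coeffs: Coefficients,
                          planforms: dict[str, WingPlanform],
                          n_elements: int = 20,
                          include_added_mass: bool = True
                          ) -> ForceDecomposition:
    """Time-resolved lift / drag / added-mass decomposition per wing.

    The stroke-averaged vertical shares are reported as percentages of the
    total predicted vertical force and sum to 100 exactly (the decomposition
    is a partition of the total).  With ``include_added_mass`` disabled the
    added-mass contribution (and hence its share) is zero.
    """
    if not std.is_periodic:
        raise ValueError("standard wingbeat must be strictly periodic")
    frame = std.frame()
    R_body = euler_zyx(*frame.euler[0])
    lift, drag, added, total = {}, {}, {}, {}
    lift_b, drag_b, added_b = {}, {}, {}
    for side in ("left", "right"):
        pf = planforms[side]
        elements = discretize_planform(pf, n_elements)
        st = wing_states(frame, side, elements, pf.wing_base_offset,
                         coeffs.f_ref)
        L, D = quasi_steady_forces(st, coeffs)
        A = added_mass_normal(st) if include_added_mass \
            else np.zeros_like(L)
        lift[side] = L.sum(axis=1)
        drag[side] = D.sum(axis=1)
        added[side] = A.sum(axis=1)
        total[side] = lift[side] + drag[side] + added[side]
        lift_b[side] = lift[side] @ R_body
        drag_b[side] = drag[side] @ R_body
        added_b[side] = added[side] @ R_body
    z_lift = sum(lift[s][:, 2].mean() for s in lift)
    z_drag = sum(drag[s][:, 2].mean() for s in drag)
    z_added = sum(added[s][:, 2].mean() for s in added)
    z_total = z_lift + z_drag + z_added
    share = {"lift": 100.0 * z_lift / z_total,
             "added_mass": 100.0 * z_added / z_total,
             "drag": 100.0 * z_drag / z_total}
    return ForceDecomposition(phase=frame.phase, lift=lift, drag=drag,
                              added_mass=added, total=total,
                              lift_body=lift_b, drag_body=drag_b,
                              added_mass_body=added_b, vertical_share=share)
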