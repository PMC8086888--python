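"""Wing planform representation and blade-element discretization.

A wing is described by its length R and a set of spanwise stations giving the
local chord and the chordwise position of the spanwise rotation axis (the
wing-base to wing-tip line about which pitch is defined).  For force
calculations the wing is split into ``n`` equally spaced chordwise blade
elements (default 20) with chord and axis offset interpolated at the element
centres (midpoint rule).

Sign convention: ``axis_offset_le`` is the distance from the spanwise axis to
the leading edge, positive when the leading edge lies ahead of the axis.  The
signed distance of the fraction-``f`` chord point (measured back from the
leading edge) from the axis is then ``f * c - axis_offset_le``, positive
toward the trailing edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WingPlanform",
    "BladeElementGeometry",
    "AirBody",
    "discretize_planform",
    "chord_point_offset",
    "elliptical_planform",
]

GRAVITY = 9.81  # m s^-2, magnitude; acts along -Z in the lab frame


@dataclass(frozen=True)
class AirBody:
    """Inertial and fluid constants: body mass, air density, gravity."""

    mass: float  # kg
    rho: float = 1.18  # kg m^-3
    g: float = GRAVITY

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.rho <= 0:
            raise ValueError("air density must be positive")

    @property
    def gravity_vector(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.g])

    @property
    def weight(self) -> float:
        return self.mass * self.g


@dataclass(frozen=True)
class WingPlanform:
    """Wing outline: span stations with chord and rotation-axis offset.

    Parameters
    ----------
    length : float
        Wing length R from base to tip, metres.
    r : array
        Spanwise station coordinates covering [0, R], metres.
    chord : array
        Local chord at each station, metres.
    axis_offset_le : array
        Perpendicular distance from the spanwise rotation axis to the leading
        edge at each station, metres, positive toward the leading edge.
    side : str
        ``"left"`` or ``"right"``.
    wing_base_offset : array
        Wing-base position in body axes, metres.
    """

    length: float
    r: np.ndarray
    chord: np.ndarray
    axis_offset_le: np.ndarray
    side: str = "right"
    wing_base_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        object.__setattr__(self, "chord", np.asarray(self.chord, dtype=float))
        object.__setattr__(
            self, "axis_offset_le",
            np.asarray(self.axis_offset_le, dtype=float))
        object.__setattr__(
            self, "wing_base_offset",
            np.asarray(self.wing_base_offset, dtype=float))
        if self.length <= 0:
            raise ValueError("wing length must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if np.any(self.r < -1e-12) or np.any(self.r > self.length + 1e-12):
            raise ValueError("stations must lie within [0, R]")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("stations must be strictly increasing")
        interior = (self.r > 0) & (self.r < self.length)
        if np.any(self.chord[interior] <= 0):
            raise ValueError("chord must be positive at interior stations")


@dataclass(frozen=True)
class BladeElementGeometry:
    """One chordwise strip of the discretized wing."""

    i: int  # element index, 1-based
    r: float  # radial coordinate of the element centre, m
    chord: float  # local chord, m
    dr: float  # element width, m
    axis_offset_le: float  # axis-to-leading-edge distance, m

    @property
    def d_half(self) -> float:
        """Signed axis distance of the half-chord point (added-mass point)."""
        return chord_point_offset(self, 0.5)

    def d_ref(self, f: float) -> float:
        """Signed axis distance of the fraction-``f`` chord point."""
        return chord_point_offset(self, f)


def chord_point_offset(element: BladeElementGeometry, f: float) -> float:
    """Signed distance from the spanwise axis to the fraction-``f`` chord point.

    ``f`` is measured back from the leading edge; the result is positive
    toward the trailing edge.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"chord fraction must lie in [0, 1], got {f}")
    return f * element.chord - element.axis_offset_le


def discretize_planform(planform: WingPlanform,
                        n_elements: int = 20) -> list[BladeElementGeometry]:
    """Split the wing into ``n_elements`` equal-width blade elements.

    Chord and axis offset are linearly interpolated at the element centres
    ``r_i = (i - 1/2) R / n``; the element width is ``dr = R / n`` so that the
    widths sum exactly to the wing length.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if planform.r[0] > 1e-9 or planform.r[-1] < planform.length - 1e-9:
        raise ValueError("planform stations must cover the full span [0, R]")
    dr = planform.length / n_elements
    centres = (np.arange(n_elements) + 0.5) * dr
    chords = np.interp(centres, planform.r, planform.chord)
    offsets = np.interp(centres, planform.r, planform.axis_offset_le)
    return [
        BladeElementGeometry(i=i + 1, r=float(centres[i]),
                             chord=float(chords[i]), dr=dr,
                             axis_offset_le=float(offsets[i]))
        for i in range(n_elements)
    ]


def elliptical_planform(length: float = 9.5e-3,
                        mean_chord: float = 3.0e-3,
                        axis_fraction: float = 0.30,
                        side: str = "right",
                        wing_base_offset=None,
                        n_stations: int = 41) -> WingPlanform:
    """Synthetic half-elliptical planform used as the default wing shape.

    The chord varies as ``c(r) = c_root * sqrt(1 - (r/R)^2)`` scaled so the
    mean chord over the span equals ``mean_chord``; the spanwise rotation axis
    sits at ``axis_fraction`` of the local chord behind the leading edge
    (default 30%, a typical insect torsion-axis location).
    """
    r = np.linspace(0.0, length, n_stations)
    shape = np.sqrt(np.clip(1.0 - (r / length) ** 2, 0.0, None))
    c_root = mean_chord / (np.pi / 4.0)  # mean of sqrt(1-x^2) on [0,1] = pi/4
    chord = c_root * shape
    if wing_base_offset is None:
        wing_base_offset = np.zeros(3)
    return WingPlanform(
        length=length, r=r, chord=chord,
        axis_offset_le=axis_fraction * chord,
        side=side, wing_base_offset=np.asarray(wing_base_offset, dtype=float))
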