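"""Elementary rotations and their analytic time derivatives.

The blade-element kinematic chain (body -> wing base -> stroke/deviation ->
spanwise pitch) is a product of single-axis rotations whose angles are known
together with their first and second time derivatives.  Everything here is
vectorized: an angle array of shape ``(...)`` yields matrix arrays of shape
``(..., 3, 3)``, so a whole wingbeat (100 phases x 20 elements) is one call.

Rotation matrices map component vectors from the rotated (child) frame to the
parent frame, i.e. ``v_parent = R @ v_child``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rot",
    "rot_derivs",
    "compose",
    "euler_zyx",
    "euler_zyx_derivs",
    "angular_velocity",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def _trig(angle):
    return np.cos(angle), np.sin(angle)


def rot(axis: str, angle: np.ndarray) -> np.ndarray:
    """Single-axis rotation matrix, shape ``angle.shape + (3, 3)``."""
    angle = np.asarray(angle, dtype=float)
    c, s = _trig(angle)
    R = np.zeros(angle.shape + (3, 3))
    if axis == "x":
        R[..., 0, 0] = 1.0
        R[..., 1, 1] = c
        R[..., 1, 2] = -s
        R[..., 2, 1] = s
        R[..., 2, 2] = c
    elif axis == "y":
        R[..., 1, 1] = 1.0
        R[..., 0, 0] = c
        R[..., 0, 2] = s
        R[..., 2, 0] = -s
        R[..., 2, 2] = c
    elif axis == "z":
        R[..., 2, 2] = 1.0
        R[..., 0, 0] = c
        R[..., 0, 1] = -s
        R[..., 1, 0] = s
        R[..., 1, 1] = c
    else:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    return R


def _rot_dangle(axis: str, angle: np.ndarray) -> np.ndarray:
    """dR/d(angle) for a single-axis rotation."""
    angle = np.asarray(angle, dtype=float)
    c, s = _trig(angle)
    D = np.zeros(angle.shape + (3, 3))
    if axis == "x":
        D[..., 1, 1] = -s
        D[..., 1, 2] = -c
        D[..., 2, 1] = c
        D[..., 2, 2] = -s
    elif axis == "y":
        D[..., 0, 0] = -s
        D[..., 0, 2] = c
        D[..., 2, 0] = -c
        D[..., 2, 2] = -s
    elif axis == "z":
        D[..., 0, 0] = -s
        D[..., 0, 1] = -c
        D[..., 1, 0] = c
        D[..., 1, 1] = -s
    else:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    return D


def rot_derivs(axis: str, angle, rate, accel):
    """Rotation matrix and its first/second *time* derivatives.

    Uses the chain rule: ``Rdot = dR/da * adot`` and
    ``Rddot = d2R/da2 * adot**2 + dR/da * addot``, where ``d2R/da2 = -R`` on
    the rotating 2x2 block (and zero on the fixed axis row/column), which is
    conveniently obtained as ``dD/da`` with D the angle derivative.
    """
    angle = np.asarray(angle, dtype=float)
    rate = np.asarray(rate, dtype=float)
    accel = np.asarray(accel, dtype=float)
    R = rot(axis, angle)
    D = _rot_dangle(axis, angle)
    # second angle derivative: differentiating D analytically equals rotating
    # the oscillatory block by a further 90 deg, i.e. dD/da = D(angle + pi/2)
    # restricted to the same sparsity; computed directly:
    D2 = _rot_dangle(axis, angle + np.pi / 2.0)
    Rd = D * rate[..., None, None]
    Rdd = D2 * (rate**2)[..., None, None] + D * accel[..., None, None]
    return R, Rd, Rdd


def compose(*terms):
    """Product of rotation triples with product-rule derivatives.

    Each term is a tuple ``(R, Rd, Rdd)``; returns the same triple for the
    left-to-right matrix product.
    """
    A, Ad, Add = terms[0]
    for B, Bd, Bdd in terms[1:]:
        AB = A @ B
        ABd = Ad @ B + A @ Bd
        ABdd = Add @ B + 2.0 * (Ad @ Bd) + A @ Bdd
        A, Ad, Add = AB, ABd, ABdd
    return A, Ad, Add


def euler_zyx(yaw, pitch, roll) -> np.ndarray:
    """Body-to-lab rotation from intrinsic Z-Y'-X'' (yaw-pitch-roll) angles."""
    return rot("z", yaw) @ rot("y", pitch) @ rot("x", roll)


def euler_zyx_derivs(angles, rates, accels):
    """Triple ``(R, Rd, Rdd)`` for the yaw-pitch-roll body rotation.

    ``angles``, ``rates``, ``accels`` are arrays of shape ``(..., 3)`` in the
    order (yaw, pitch, roll).
    """
    angles = np.asarray(angles, dtype=float)
    rates = np.asarray(rates, dtype=float)
    accels = np.asarray(accels, dtype=float)
    return compose(
        rot_derivs("z", angles[..., 0], rates[..., 0], accels[..., 0]),
        rot_derivs("y", angles[..., 1], rates[..., 1], accels[..., 1]),
        rot_derivs("x", angles[..., 2], rates[..., 2], accels[..., 2]),
    )


def angular_velocity(R: np.ndarray, Rd: np.ndarray) -> np.ndarray:
    """Angular velocity vector (lab components) from R and Rdot.

    ``Omega_skew = Rd @ R.T``; returns the axial vector of the skew part.
    """
    W = Rd @ np.swapaxes(R, -1, -2)
    return np.stack(
        [W[..., 2, 1] - W[..., 1, 2],
         W[..., 0, 2] - W[..., 2, 0],
         W[..., 1, 0] - W[..., 0, 1]],
        axis=-1,
    ) / 2.0
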