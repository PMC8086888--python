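"""Shared fixtures: small synthetic datasets and reference geometries."""

import numpy as np
import pytest

import flapforce as ff
from flapforce.kinematics import N_PHASE, WingbeatFrame
from flapforce.morphology import WingPlanform


@pytest.fixture(scope="session")
def gen_params():
    return ff.GeneratorParams()


@pytest.fixture(scope="session")
def planforms(gen_params):
    return ff.default_planforms(gen_params)


@pytest.fixture(scope="session")
def hover_frame(gen_params):
    """One analytic hovering wingbeat (exact derivatives, body at rest)."""
    return ff.analytic_frames(gen_params, n_wingbeats=1)[0]


@pytest.fixture(scope="session")
def manoeuvre_frames():
    """Analytic wingbeats with body translation and per-beat variation."""
    p = ff.GeneratorParams(body_programme="const_accel",
                           wingbeats_per_sequence=6)
    return ff.analytic_frames(p, n_wingbeats=6)


@pytest.fixture(scope="session")
def processed_manoeuvre(manoeuvre_frames, planforms):
    return ff.frames_to_processed(manoeuvre_frames, planforms)


@pytest.fixture(scope="session")
def rect_planform():
    """Rectangular 3 mm x 10 mm wing, pitch axis 30% behind leading edge."""
    return WingPlanform(length=0.010, r=[0.0, 0.010],
                        chord=[0.003, 0.003],
                        axis_offset_le=[0.0009, 0.0009])


def static_frame(chord_pitch=0.0, body_vel=(0.0, 0.0, 0.0),
                 body_acc=(0.0, 0.0, 0.0), period=0.005):
    """Frame with constant wing angles and uniform body translation."""
    z3 = np.zeros((N_PHASE, 3))
    zz = np.zeros(N_PHASE)
    wing = {k + s: zz.copy() for k in ("phi", "theta", "omega0", "omega_r")
            for s in ("", "_d", "_dd")}
    wing["omega0"] = np.full(N_PHASE, chord_pitch)
    t = np.arange(N_PHASE) / N_PHASE * period
    vel = np.tile(np.asarray(body_vel, float), (N_PHASE, 1))
    acc = np.tile(np.asarray(body_acc, float), (N_PHASE, 1))
    pos = t[:, None] * vel + 0.5 * t[:, None] ** 2 * acc
    vel = vel + t[:, None] * acc
    return WingbeatFrame(
        n=0, t=t, period=period, body_pos=pos, body_vel=vel, body_acc=acc,
        euler=z3.copy(), euler_d=z3.copy(), euler_dd=z3.copy(),
        wings={"left": {k: v.copy() for k, v in wing.items()},
               "right": {k: v.copy() for k, v in wing.items()}},
        mass=1.0e-4, rho=1.2)


@pytest.fixture
def translation_frame():
    return static_frame(body_vel=(-1.0, 0.0, 0.0))
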