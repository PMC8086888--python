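"""Estimation of the aerodynamic force coefficients by linear least squares.

The model's stroke-averaged force is affine-linear in the two unknown
coefficients, so for every wingbeat the measured stroke-averaged aerodynamic
force (mass times body acceleration minus weight) minus the added-mass sum
gives three linear equations

    F_meas(n) - Sigma_A(n) = C_Pa Sigma_P(n) + C_D0 Sigma_D(n) + eps(n)

solved through the origin over all wingbeats.  The module also provides the
model ablations (no drag offset, no added mass, flat-plate wing, static
body), the exhaustive chordwise-reference search with the physical constraint
C_D0 >= 0, sequence-level subsampling, and per-axis goodness of fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .bladeforces import Coefficients, StrokeSums, frame_stroke_sums
from .kinematics import WingbeatFrame
from .morphology import AirBody, WingPlanform
from .rotations import euler_zyx

__all__ = [
    "MeasuredForce",
    "ProcessedWingbeat",
    "FitResult",
    "SubsampleDistribution",
    "measured_stroke_force",
    "assemble_regression",
    "fit_coefficients",
    "ablation_variants",
    "chord_reference_search",
    "subsample_fits",
    "goodness_of_fit",
    "fit_dataset",
]


@dataclass
class MeasuredForce:
    """Measured stroke-averaged aerodynamic force for one wingbeat (N, lab)."""

    n: int
    F_lab: np.ndarray  # (3,)
    R_body: np.ndarray | None = None  # mean body orientation (body -> lab)

    @property
    def F_body(self) -> np.ndarray:
        if self.R_body is None:
            raise ValueError("no body orientation attached")
        return self.R_body.T @ self.F_lab


def measured_stroke_force(frame: WingbeatFrame,
                          air: AirBody | None = None) -> MeasuredForce:
    """Mass times (stroke-mean acceleration minus gravity), in lab axes."""
    if air is None:
        if frame.mass is None:
            raise ValueError("frame carries no mass and no AirBody was given")
        air = AirBody(mass=frame.mass, rho=frame.rho)
    acc = frame.mean_body_acc()
    F = air.mass * (acc - air.gravity_vector)
    R = euler_zyx(*frame.euler.mean(axis=0))
    return MeasuredForce(n=frame.n, F_lab=F, R_body=R)


@dataclass
class ProcessedWingbeat:
    """One wingbeat ready for regression: frame, geometry, sums, measurement."""

    frame: WingbeatFrame
    planforms: dict[str, WingPlanform]
    measured: MeasuredForce
    sums: dict[str, StrokeSums]  # 'left', 'right', 'LR'
    sequence_id: str = "seq0"

    def recompute_sums(self, f_ref: float = 0.75, n_elements: int = 20,
                       flat_plate: bool = False,
                       no_body_motion: bool = False) -> dict[str, StrokeSums]:
        frame = self.frame
        if flat_plate:
            frame = _flat_plate_frame(frame, self.planforms)
        if no_body_motion:
            frame = _static_body_frame(frame)
        return frame_stroke_sums(frame, self.planforms, n_elements, f_ref)


def _flat_plate_frame(frame: WingbeatFrame,
                      planforms: dict[str, WingPlanform]) -> WingbeatFrame:
    """Freeze the spanwise twist: pitch set uniformly to its mid-span value."""
    wings = {}
    for side, w in frame.wings.items():
        r_mid = planforms[side].length / 2.0
        w2 = dict(w)
        for suffix in ("", "_d", "_dd"):
            w2["omega0" + suffix] = (w["omega0" + suffix]
                                     + w["omega_r" + suffix] * r_mid)
            w2["omega_r" + suffix] = np.zeros_like(w["omega_r" + suffix])
        wings[side] = w2
    return replace(frame, wings=wings)


def _static_body_frame(frame: WingbeatFrame) -> WingbeatFrame:
    """Drop the body's translational and rotational motion from the chain."""
    z = np.zeros_like(frame.body_vel)
    return replace(frame, body_vel=z, body_acc=z.copy(),
                   euler_d=np.zeros_like(frame.euler_d),
                   euler_dd=np.zeros_like(frame.euler_dd))


# ---------------------------------------------------------------------------
# Regression assembly and solution
# ---------------------------------------------------------------------------

def assemble_regression(wingbeats, subtract_added_mass: bool = True):
    """Stack the per-wingbeat design blocks (wingbeat-major, axes X, Y, Z).

    ``wingbeats`` is a sequence of ``(MeasuredForce, StrokeSums)`` pairs (the
    combined two-wing sums).  Returns ``(X, y)`` with ``X`` of shape
    ``(3 N, 2)`` holding the Sigma_P and Sigma_D columns and ``y`` the
    response with the added-mass sum moved to the left-hand side.
    """
    wingbeats = list(wingbeats)
    if not wingbeats:
        raise ValueError("need at least one wingbeat")
    X = np.empty((3 * len(wingbeats), 2))
    y = np.empty(3 * len(wingbeats))
    for j, (meas, sums) in enumerate(wingbeats):
        rows = slice(3 * j, 3 * j + 3)
        X[rows, 0] = sums.sigma_P
        X[rows, 1] = sums.sigma_D
        resp = meas.F_lab - (sums.sigma_A if subtract_added_mass else 0.0)
        y[rows] = resp
    return X, y


@dataclass
class FitResult:
    """Estimated coefficients with residual diagnostics."""

    C_P_alpha_hat: float
    C_D0_hat: float
    residuals: np.ndarray  # (N, 3) lab-axis residuals per wingbeat
    mse: float  # (1 / 3N) sum eps . eps
    n_params: int
    variant: str = "full"
    f_ref: float = 0.75
    constrained: bool = False  # True when the C_D0 >= 0 bound is active
    C_D0_unconstrained: float | None = None  # pre-constraint estimate
    fitted: np.ndarray | None = None  # (N, 3) model forces, lab axes
    goodness: dict | None = None  # per-axis (slope, intercept, R^2)

    @property
    def coefficients(self) -> Coefficients:
        return Coefficients(self.C_P_alpha_hat, max(self.C_D0_hat, 0.0),
                            self.f_ref)


def fit_coefficients(X: np.ndarray, y: np.ndarray,
                     include_offset: bool = True,
                     constrain_nonneg: bool = True,
                     variant: str = "full",
                     f_ref: float = 0.75) -> FitResult:
    """Ordinary least squares through the origin for (C_Pa, C_D0).

    With ``constrain_nonneg``, a negative unconstrained drag offset is
    handled by refitting with C_D0 fixed at zero (the active-constraint
    solution of the one-sided bound, equivalent to non-negative least squares
    for a single bounded parameter).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (3N, 2) and y (3N,)")
    if X.shape[0] % 3:
        raise ValueError("rows must come in wingbeat blocks of three axes")

    def solve(cols):
        A = X[:, cols]
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient regression design")
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return beta

    constrained = False
    cd0_raw = None
    if include_offset:
        beta = solve([0, 1])
        cp, cd0 = float(beta[0]), float(beta[1])
        cd0_raw = cd0
        if constrain_nonneg and cd0 < 0.0:
            cp = float(solve([0])[0])
            cd0 = 0.0
            constrained = True
        n_params = 2
    else:
        cp = float(solve([0])[0])
        cd0 = 0.0
        n_params = 1

    fitted_rows = X[:, 0] * cp + X[:, 1] * cd0
    eps = (y - fitted_rows).reshape(-1, 3)
    mse = float(np.sum(eps * eps) / eps.size)
    return FitResult(C_P_alpha_hat=cp, C_D0_hat=cd0, residuals=eps, mse=mse,
                     n_params=n_params, variant=variant, f_ref=f_ref,
                     constrained=constrained, C_D0_unconstrained=cd0_raw,
                     fitted=fitted_rows.reshape(-1, 3))


def fit_dataset(dataset: list[ProcessedWingbeat],
                include_offset: bool = True,
                constrain_nonneg: bool = True,
                variant: str = "full",
                f_ref: float = 0.75,
                sums_key: str = "LR",
                subtract_added_mass: bool = True,
                with_goodness: bool = False) -> FitResult:
    """Fit the coefficients to a processed dataset (convenience wrapper)."""
    pairs = [(wb.measured, wb.sums[sums_key]) for wb in dataset]
    X, y = assemble_regression(pairs, subtract_added_mass)
    res = fit_coefficients(X, y, include_offset, constrain_nonneg,
                           variant, f_ref)
    if with_goodness and len(dataset) >= 3:
        res.goodness = _dataset_goodness(dataset, res, subtract_added_mass)
    return res


def _dataset_goodness(dataset, res, subtract_added_mass=True):
    """Per-body-axis goodness of the full model force against measurement."""
    fitted, measured = [], []
    for wb, f in zip(dataset, res.fitted):
        model_lab = f + (wb.sums["LR"].sigma_A if subtract_added_mass else 0.0)
        R = wb.measured.R_body
        fitted.append(R.T @ model_lab)
        measured.append(R.T @ wb.measured.F_lab)
    return goodness_of_fit(np.array(fitted), np.array(measured))


# ---------------------------------------------------------------------------
# Ablations and chordwise-reference search
# ---------------------------------------------------------------------------

ABLATION_LABELS = ("full", "no drag offset", "no drag offset or added mass",
                   "flat plate wing", "no body motion")


def ablation_variants(dataset: list[ProcessedWingbeat],
                      f_ref: float = 0.75,
                      n_elements: int = 20) -> list[FitResult]:
    """Fit the full model and its four standard simplifications.

    Variants: drop the drag-offset column; additionally drop the added-mass
    sum from the response; recompute the kinematics with the pitch angle set
    uniformly to its mid-span value (flat-plate wing); recompute them with
    the body held static.
    """
    results = [fit_dataset(dataset, variant="full", f_ref=f_ref)]
    results.append(fit_dataset(dataset, include_offset=False,
                               variant="no drag offset", f_ref=f_ref))
    results.append(fit_dataset(dataset, include_offset=False,
                               subtract_added_mass=False,
                               variant="no drag offset or added mass",
                               f_ref=f_ref))
    for label, kwargs in (("flat plate wing", {"flat_plate": True}),
                          ("no body motion", {"no_body_motion": True})):
        pairs = []
        for wb in dataset:
            sums = wb.recompute_sums(f_ref=f_ref, n_elements=n_elements,
                                     **kwargs)
            pairs.append((wb.measured, sums["LR"]))
        X, y = assemble_regression(pairs)
        results.append(fit_coefficients(X, y, variant=label, f_ref=f_ref))
    return results


def chord_reference_search(dataset: list[ProcessedWingbeat],
                           grid=None,
                           n_elements: int = 20):
    """Exhaustive search for the chordwise reference point minimizing MSE.

    At each candidate fraction the stroke sums are recomputed, the model is
    refitted subject to C_D0 >= 0, and the fraction with the smallest MSE is
    returned together with the full profile of results.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.951, 0.01), 4)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty chordwise search grid")
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("chord fractions must lie in [0, 1]")
    profile = []
    for f in grid:
        pairs = []
        for wb in dataset:
            sums = wb.recompute_sums(f_ref=f, n_elements=n_elements)
            pairs.append((wb.measured, sums["LR"]))
        X, y = assemble_regression(pairs)
        profile.append(fit_coefficients(X, y, constrain_nonneg=True,
                                        variant="chord search", f_ref=float(f)))
    best = int(np.argmin([r.mse for r in profile]))
    return float(grid[best]), profile[best], profile


# ---------------------------------------------------------------------------
# Subsampling and goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class SubsampleDistribution:
    """Coefficient estimates over repeated sequence-level subsamples."""

    reps: int
    frac: float
    estimates: np.ndarray  # (reps, 2) columns C_Pa, C_D0
    rng_seed: int

    @property
    def sd(self) -> np.ndarray:
        return self.estimates.std(axis=0, ddof=1)

    @property
    def mean(self) -> np.ndarray:
        return self.estimates.mean(axis=0)


def subsample_fits(dataset: list[ProcessedWingbeat],
                   frac: float = 0.10,
                   reps: int = 1000,
                   seed: int = 0) -> SubsampleDistribution:
    """Refit on random subsets of flight sequences (never single wingbeats)."""
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    seq_ids = sorted({wb.sequence_id for wb in dataset})
    by_seq = {s: [wb for wb in dataset if wb.sequence_id == s]
              for s in seq_ids}
    n_draw = math.ceil(frac * len(seq_ids))
    rng = np.random.default_rng(seed)
    est = np.empty((reps, 2))
    for rep in range(reps):
        chosen = rng.choice(len(seq_ids), size=n_draw, replace=False)
        sub = [wb for i in chosen for wb in by_seq[seq_ids[i]]]
        res = fit_dataset(sub)
        est[rep] = (res.C_P_alpha_hat, res.C_D0_hat)
    return SubsampleDistribution(reps=reps, frac=frac, estimates=est,
                                 rng_seed=seed)


def goodness_of_fit(fitted: np.ndarray, measured: np.ndarray) -> dict:
    """Per-axis regression of fitted on measured force, intercept included.

    Returns ``{axis: {"slope", "intercept", "r2", "degenerate"}}``; R^2 is
    the squared correlation and is flagged undefined when the measured axis
    has zero variance.
    """
    fitted = np.asarray(fitted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if fitted.shape != measured.shape or fitted.ndim != 2 \
            or fitted.shape[1] != 3:
        raise ValueError("fitted and measured must both be (N, 3)")
    if fitted.shape[0] < 3:
        raise ValueError("need >= 3 wingbeats for goodness of fit")
    out = {}
    for axis, name in enumerate(("x", "y", "z")):
        m = measured[:, axis]
        fhat = fitted[:, axis]
        var_m = np.var(m)
        if var_m == 0.0:
            out[name] = {"slope": np.nan, "intercept": np.nan,
                         "r2": np.nan, "degenerate": True}
            continue
        slope, intercept = np.polyfit(m, fhat, 1)
        var_f = np.var(fhat)
        cov = np.mean((m - m.mean()) * (fhat - fhat.mean()))
        r2 = cov**2 / (var_m * var_f) if var_f > 0 else 0.0
        out[name] = {"slope": float(slope), "intercept": float(intercept),
                     "r2": float(r2), "degenerate": False}
    return out
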