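# Methods

## Model

The aerodynamic model treats each wing as 20 independent chordwise blade
elements of equal width Δr = R/20, with chord c(i) and rotation-axis offset
interpolated at the element centres (midpoint rule). Element kinematics are
measured in the laboratory frame through the rigid chain

    lab ← body (yaw–pitch–roll, intrinsic Z-Y′-X″) ← wing base
        ← stroke rotation φ about z ← deviation rotation θ about x
        ← spanwise pitch rotation ω(r) = ω₀ + ω_r·r about the span

so that the body's translation and rotation are folded into the relative
wind of every element. The left wing is described in a left-handed frame;
internally it is handled by inserting a body x–z reflection after the body
rotation so one right-handed code path serves both sides. The chain is
differentiated analytically (twice) by the product rule on single-axis
rotation matrices; a central-finite-difference oracle over an independently
posed position chain verifies velocity and acceleration to ~1e-6 relative in
the tests.

Aerodynamic speed U and angle of attack α are measured at a chordwise
reference point, by default the three-quarter chord point working back from
the leading edge. This is the classical location at which measuring the
local incidence folds small-amplitude rotational (pitch-rate) effects into
the translational force laws, so no separate "rotational lift" term is
needed. The relative wind has its spanwise component removed before
computing U and α; α is kept in [0, π/2] and the side information (which
surface is the suction side) is carried entirely by the signed unit vectors:
u_par along the relative flow (drag direction), u_perp perpendicular to flow
and span toward increasing α (lift direction), and the chord-plane normal
u_norm signed so that u_norm·(relative wind) ≥ 0. These satisfy the exact
identity u_norm = u_perp·cos α + u_par·sin α, which is what lets the
stroke-averaged lift-plus-drag sum collapse into a part linear in C_Pα
(along u_norm, weighted by sin α) and a part linear in C_D0 (along u_par).

The lift and drag coefficients are modelled as

    C_L = C_Pα sin α cos α
    C_D = C_Pα sin²α + C_D0

i.e. a single pressure-force scaling plus a constant drag offset absorbing
friction and residual pressure drag at zero incidence. Equivalently, with
(C_Pα, C_D0) = (2.70, 0.15), C_L = 1.35 sin 2α and C_D = 1.50 − 1.35 cos 2α
— the trigonometric double-angle form that simpler empirical polars
approximate.

### Added mass

The thin-plate added-mass force per element is −(π/4)ρc²·a_n·Δr along the
surface normal, where a_n is the surface-normal acceleration of the
half-chord point. We evaluate a_n as the inertial-frame rate of change of
the surface-normal velocity, a_n = n̂·a + Ω_r·(ŝ×n̂)·v, where Ω_r is the pitch
rate about the span. The second (rotation-coupling) term vanishes for a
non-pitching element; including it makes the normal force, together with the
chordwise "centripetal" component (π/4)ρc²Ω_r·U′⊥S·Δr, the exact negative
rate of change of the added fluid momentum. Consequently the two components
integrate to numerical zero over any strictly periodic rigid planar motion,
which the tests verify to better than 1e-6 of the peak force, while the
normal component alone does not. Only the surface-normal component enters
the predicted forces, following the usual blade-element convention; the
chordwise component is exposed separately as a validation oracle, and the
spanwise (finite-width) component is excluded. When the in-plane relative
wind falls below 1e-6 m s⁻¹ the element is flagged degenerate and the
quasi-steady force is dropped (its U² prefactor vanishes anyway); the
added-mass force is retained.

## Kinematics processing

Raw channels are smoothed with quintic smoothing splines whose residual sum
of squares is tied to the variation a zero-phase third-order Butterworth
filter would remove: 100 Hz cut-off for body position and orientation,
500 Hz for the wing-tip angles, 800 Hz for the twist channels (all
configurable). The filter is applied forward–backward with a long
odd-reflection pad (ten filter time constants) so the tolerance reflects the
steady-state response rather than edge transients; a signal entirely below
the cut-off therefore gets an (effectively) interpolating spline. The
smoothing spline itself is a penalized B-spline regression with knots at the
data sites and an exactly integrated third-derivative roughness penalty; the
penalty is chosen by bisection until the residual matches the tolerance to
1e-6 relative. Derivatives up to second order are analytic.

Wingbeats are delimited at local minima of the mean of the two wings' tip
angular speed √(φ̇²cos²θ + θ̇²); a full wingbeat runs from one downstroke
start to the next, the downstroke being the half-stroke on which the stroke
angle decreases (configurable sign convention, since only the geometric
definition of φ is fixed). Shallow double minima closer than a quarter of
the typical half-stroke are merged, keeping the candidate nearest a reversal
of the mean stroke rate. Each wingbeat is then resampled at 100 evenly
spaced phases (values and both derivatives evaluated from the splines, which
for ~3800 Hz video is an upsampling factor of about five), and optionally
compressed into a truncated Fourier series plus cubic polynomial in time
from the wingbeat start — first order for body channels, fourth for tip
angles, sixth for twist — fitted by plain least squares on the 100 samples.
For compliant signals this preserves >99.99% of the variance.

## Estimation

For every wingbeat, the three lab-axis components of the measured
stroke-averaged aerodynamic force (mass × stroke-mean acceleration minus
weight) minus the combined two-wing added-mass sum give three rows of a
regression through the origin on the two predictor columns Σ_Pα and Σ_D0.
The physical bound C_D0 ≥ 0 is enforced by refitting with C_D0 = 0 when the
unconstrained estimate is negative (the active-constraint solution of
single-parameter non-negative least squares). Goodness of fit is reported
per body axis by regressing fitted on measured forces with an intercept
(R² is the squared correlation), since a through-origin regression has no
well-defined R². Model ablations drop the offset column, additionally drop
the added-mass correction, freeze the spanwise twist at its mid-span value
(flat-plate wing), or zero the body's velocity, acceleration and angular
rates in the kinematic chain (static body). The chordwise reference point is
optimized by exhaustive search over a 1%-step grid (default 0.50–0.95),
refitting the constrained model at each candidate. Parameter uncertainty is
assessed by refitting on random subsamples of flight sequences (never of
individual wingbeats, which would break the serial dependence structure); no
autocorrelation correction is applied.

## Standard hovering wingbeat

Near-hover wingbeats are those with stroke-averaged body acceleration
strictly below 0.5 m s⁻² both vertically (|a_z|) and horizontally
(√(a_x²+a_y²)); of these, the slowest 1% (by stroke-averaged body speed,
ties broken by speed then index) are averaged phase by phase. The average is
refitted with the harmonic basis, the non-constant polynomial terms are
zeroed to make it strictly periodic, and the body is held stationary at the
subset's mean pitch attitude with zero roll. The time-varying model force
for this reference wingbeat is decomposed into lift, drag and added-mass
parts, and their stroke-averaged vertical components are reported as
percentages of the total (summing to 100 exactly).

## Synthetic data

The generator emulates hoverfly-scale flight: 188 Hz wingbeat frequency,
wing length 9.5 mm, mean chord 3 mm (half-elliptical planform with the
torsion axis at 30% chord), body mass 110 mg, air density 1.18 kg m⁻³, body
pitched 43.6° nose-up. Stroke and deviation angles are in-phase sinusoids
with deviation amplitude 0.9× stroke amplitude, which (after the body pitch)
gives a near-horizontal straight tip path in the laboratory. The pitch
offset oscillates half-stroke-antisymmetrically about a mean of 0.72 rad
(the chord tracking the inclined path) with a fundamental-plus-third-
harmonic waveform, producing a mid-stroke angle-of-attack plateau near
30° with rapid reversal; the linear twist gradient oscillates in antiphase,
flattening the tip by roughly a third relative to the root. The default
stroke half-amplitude (1.02 rad) sits at the value for which the model with
(C_Pα, C_D0) = (2.70, 0.15) supports body weight in hover;
`calibrate_hover_amplitude` recomputes this balance by bisection for any
parameter set. Manoeuvring sequences add a constant or saccade-like
(Gaussian-pulse) body acceleration of up to (4.0, 1.0, 3.5) m s⁻² — chosen
to match the few-m s⁻² stroke-averaged accelerations typical of free-flight
manoeuvres — together with optional inter-sequence stroke-amplitude
variability and a slow within-sequence amplitude modulation envelope.

"Measured" forces for recovery experiments are forward-simulated from the
model's own stroke sums plus isotropic Gaussian noise (default scale 0.2 mN,
comparable to the per-axis residual of fitting real free-flight data), which
realizes the regression's generative assumption exactly: noiseless data are
recovered to numerical precision and noisy estimates are unbiased with the
closed-form OLS sampling variance.

What passing on synthetic data does and does not show: the generator shares
the model's rigid-chain kinematics and linear-twist deformation, so
round-trip tests validate the geometry, calculus and estimation machinery —
not the physical adequacy of the two-parameter force law for real wings.
Real data contain camber, non-linear twist, wing–wake and wing–wing
interaction effects and measurement error correlated across wingbeats, none
of which are emulated; the synthetic manoeuvre variability is also milder
than that of real free flight, so the share of measured-force variance the
fit explains on synthetic noisy data is smaller than what detailed kinematic
data can achieve.

## Numerical choices and problem sizes

- 20 blade elements and 100 phase samples: refining to 1000 elements changes
  the mean predicted force on the hovering wingbeat by ~0.7%, and to 10 000
  time steps by ~0.03% (both recomputed by `scripts/acceptance.py`).
- Penalty bisection for smoothing runs in log-space to a 1e-7 relative
  residual match; tolerances at or below the roundoff floor switch to exact
  interpolation.
- Harmonic fits use ordinary least squares on the 100 resampled points; the
  projection basis is checked for rank.
- Recovery and subsampling experiments use 200 wingbeats (20 sequences of
  10); subsampling defaults to 1000 repetitions in library use and 500 in
  the acceptance script.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer per experiment.

## Known limitations

- Rotational (moment) dynamics of the body are not modelled; only the
  translational force balance is fitted.
- Body lift and drag are neglected, as is wing camber.
- The within-wingbeat force time history is a model prediction only — the
  stroke-averaged regression provides no direct constraint on it.
- The hovering decomposition's added-mass share is sensitive to the
  pitch-reversal timing of the wingbeat shape; for the default synthetic
  wingbeat it is slightly negative, whereas wingbeats with earlier pitch
  reversal give it a positive weight-support role.
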