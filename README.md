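# flapforce

Semi-empirical blade-element modelling of the aerodynamics of manoeuvring
insect flight.

`flapforce` estimates the aerodynamic forces produced by a flapping insect
from its measured wing and body kinematics. Each wing is split into 20
chordwise blade elements; at 100 phase samples per wingbeat the rigid
kinematic chain — body pose, stroke angle φ, deviation angle θ, and a linear
spanwise twist ω(r) = ω₀ + ω_r·r — is differentiated analytically to give
each element's velocity, angle of attack α (measured at the three-quarter
chord point), and half-chord-point acceleration. The instantaneous forces on
element *i* are

    L(i,t) = ½ ρ U² c (C_Pα sin α cos α) 1⊥U,r Δr        (quasi-steady lift)
    D(i,t) = ½ ρ U² c (C_Pα sin²α + C_D0) 1∥U Δr         (quasi-steady drag)
    A(i,t) = −(π/4) ρ c² U̇′⊥S 1⊥S Δr                     (added mass)

with only two free parameters: C_Pα, the derivative of the pressure-force
coefficient with angle of attack, and C_D0, the drag coefficient offset at
zero incidence. Because the stroke-averaged model force is linear in
(C_Pα, C_D0), both are estimated by linear least squares against the
"measured" stroke-averaged aerodynamic force m·(ẍ̄_b − ḡ) obtained from the
body's acceleration, through the origin, over all wingbeats:

    m ẍ̄_b(n) − m ḡ − Σ_A(n) = C_Pα Σ_Pα(n) + C_D0 Σ_D0(n) + ε(n)

The package provides the full validation machinery around this estimator —
model ablations (no drag offset, no added mass, flat-plate wing, static
body), an exhaustive search over the chordwise reference point subject to
C_D0 ≥ 0, sequence-level subsampling for parameter uncertainty, a standard
hovering wingbeat with a lift/drag/added-mass force decomposition, and
blade-element/time-step convergence checks — plus a synthetic-kinematics
generator so that every part of the pipeline is testable without
high-speed-video data.

Intended users: researchers in insect flight biomechanics, flight dynamics
and bio-inspired micro air vehicles who have (or want to simulate) wingbeat
kinematics and need fast, physically grounded force estimates.

## Worked example

```python
import flapforce as ff
from flapforce.pipeline import process_dataset
from flapforce.hovering import build_standard_wingbeat, decompose_time_forces

# 1. generate a small manoeuvring dataset (raw time series at 3800 Hz)
params = ff.GeneratorParams(n_sequences=4, wingbeats_per_sequence=5,
                            body_programme="const_accel", amp_jitter=0.03,
                            wingbeat_jitter=0.05, seed=11)
dataset = ff.make_dataset(params)
planforms = ff.default_planforms(params)

# 2. smooth, segment into wingbeats, resample at 100 phases, form stroke sums
wingbeats = process_dataset(dataset.sequences, planforms)
print(f"{len(wingbeats)} wingbeats from {params.n_sequences} sequences, "
      f"period {wingbeats[0].frame.period*1e3:.2f} ms")

# 3. forward-simulate measured stroke-averaged forces and refit the model
truth = ff.Coefficients(C_P_alpha=2.70, C_D0=0.15)
sim = ff.forward_simulate_measured(wingbeats, truth, noise_sd=0.0)
fit = ff.fit_dataset(sim)
print(f"C_Pa = {fit.C_P_alpha_hat:.4f}, C_D0 = {fit.C_D0_hat:.4f}, "
      f"MSE = {fit.mse*1e6:.2e} (mN)^2")

# 4. hovering reference wingbeat and its vertical force decomposition
hover = ff.calibrate_hover_amplitude(ff.GeneratorParams(), truth, planforms)
pool = ff.frames_to_processed(ff.analytic_frames(hover, n_wingbeats=4),
                              planforms)
std = build_standard_wingbeat(pool)
share = decompose_time_forces(std, truth, planforms).vertical_share
print(f"vertical force shares: lift {share['lift']:.1f}%, "
      f"added mass {share['added_mass']:.1f}%, drag {share['drag']:.1f}%")
```

This prints:

```
20 wingbeats from 4 sequences, period 5.31 ms
C_Pa = 2.7000, C_D0 = 0.1500, MSE = 7.91e-34 (mN)^2
vertical force shares: lift 94.0%, added mass -1.9%, drag 7.8%
```

The fit recovers the generating coefficients exactly because the forward
simulation realizes the regression's generative model without noise; the
mean squared residual is at numerical zero. The decomposition says that for
the synthetic hovering wingbeat — whose stroke amplitude is calibrated by
bisection so the model exactly supports the 1.08 mN body weight —
quasi-steady lift provides 94% of the stroke-averaged vertical force, drag
8%, and added mass a small negative share (its upstroke and downstroke
contributions nearly cancel for this wingbeat shape).

There is also a CLI mirroring the library:

```sh
flapforce simulate --out data/
flapforce fit --dataset data/ --out fit/ --ablations --chord-search
flapforce standard-wingbeat --dataset data/ --out std/
```

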