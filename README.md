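# flysim

Desk-scale biomechanical simulation toolkit for fruit-fly locomotion.

Animal behaviour emerges from the interplay of nervous system, body and
environment, and studying it in simulation requires an anatomically
grounded body model with tractable physics. `flysim` implements, at
laptop scale, the physics and analysis machinery for whole-body
*Drosophila* locomotion: an articulated 67-segment body with the
bench-measured part masses (0.983 mg total), a stateless quasi-steady
fluid model for flapping-wing aerodynamics, adhesion-augmented Coulomb
contact for walking on inclines and ceilings, an open-loop wing-beat
pattern generator, the walking reference-data pipeline (snippet
selection, swing/stance labelling, 2D→3D lifting, regularized inverse
kinematics), the standard gait and flight statistics, and the
imitation-environment contracts (steering commands, rewards,
termination, procedural terrains, low-resolution eye rendering) used to
train locomotion controllers. Synthetic generators with exact ground
truth stand in for recorded arena and flight datasets throughout the
test-suite.

## The models in brief

**Fluid forces.** A rigid ellipsoid (semi-axes a, b, c) moving with
body-frame velocity **v** and angular velocity **ω** through air
(ρ, β) feels five quasi-steady components scaled by dimensionless
coefficients c = (c_blunt, c_slender, c_angular, c_kutta, c_magnus),
default (1.0, 0.5, 1.5, 1.7, 1.0):

* viscous resistance  F = −6πβ r_D **v**,  r_D = (a+b+c)/3 (Stokes in
  the sphere limit);
* quadratic drag  F = −ρ|v| [c_blunt A_proj + c_slender (A_max −
  A_proj)] **v** with the silhouette area A_proj along the motion;
* Magnus lift  F = c_magnus ρV (**ω** × **v**);
* Kutta lift  |F| = c_kutta ρ A_max |v|² sin α cos α at angle of attack
  α, perpendicular to **v** in the plane of **v** and the chord normal;
* added mass from Lamb's potential-flow coefficients (ρV/2 per axis for
  a sphere).

**Contact and adhesion.** A contact sticks while |f∥| ≤ μ f⊥ (cone
half-angle atan μ = 45° at the default μ = 1); an adhesion actuator
injects up to one body weight along the inward normal, raising the slip
margin μf⊥ − |f∥| by exactly μ·a and allowing inverted attachment when
the summed adhesion exceeds the weight.

**Inverse kinematics.** Keypoint fitting minimizes
Σᵢ‖sᵢ(q) − sᵢ*‖² + λ‖q − q₀‖² (λ = 1e−4 cm² rad⁻², q₀ = 0) with
analytic Jacobians, Levenberg damping and joint-limit projection.

See `docs/methods.md` for the full formulation, assumptions and
numerical choices, and `docs/FORMATS.md` for file schemas.

## Worked example

```python
from flysim import units
from flysim.body import build_default_fly, total_mass
from flysim.contact import friction_cone_angle, DEFAULT_MU
from flysim.wpg import WingBeatPattern
from flysim.flight import (FlightSimulator, calibrate_fluidcoef,
                           mean_lift, tune_wing_actuator)
from flysim.fluid import FluidCoefficients

fly = build_default_fly()
print(f"segments: {fly.n_segments}")
print(f"total mass: {units.kg_to_mg(total_mass(fly)):.4f} mg")
print(f"friction cone half-angle: {friction_cone_angle(DEFAULT_MU):.0f} deg")

pattern = WingBeatPattern.synthetic_hover()          # 218 Hz baseline
servo = tune_wing_actuator(pattern, tolerance=0.05)  # gain search
print(f"tuned wing gain: {servo.gain[0]:.3e} N m/rad")

coeffs = calibrate_fluidcoef(FluidCoefficients(), pattern, servo)
print(f"calibrated fluidcoef: {[round(float(c), 3) for c in coeffs.as_array()]}")

sim = FlightSimulator(servo=servo, coeffs=coeffs)
lift, _ = mean_lift(sim, pattern)
print(f"mean lift / weight: {lift / sim.weight:.4f}")
```

prints (about a dozen seconds on one core):

```
segments: 67
total mass: 0.9832 mg
friction cone half-angle: 45 deg
tuned wing gain: 1.242e-04 N m/rad
calibrated fluidcoef: [1.0, 0.5, 1.5, 2.398, 1.0]
mean lift / weight: 0.9999
```

The body has the full 67-segment composition and the per-part masses
sum to 0.983 mg. Servo tuning doubles the (shared) wing gain until the
wings replay the baseline pattern with a mean absolute error below 5%
of the wing-angle amplitude; calibration then scales the Kutta-lift
coefficient until the cycle-averaged vertical fluid force balances body
weight — here to 0.01%, with the drag coefficients untouched.

## Command line

```sh
flysim body build --out out/              # body YAML (67 segments)
flysim flight hover --cycles 10 --out out/   # trajectory + force traces
flysim walk prep --speed 2 --seed 1 --out out/  # snippets: select,
                                                # resample, label, lift
flysim env bump --seed 3 --out out/       # procedural bump heightfield
flysim synth walk --speed 2 --seed 1 --out out/  # synthetic arena track
```

Every command takes `--config file.yaml --seed N --out dir
--log-level L`; exit codes are 0 (success), 2 (contract error),
3 (calibration failure).

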