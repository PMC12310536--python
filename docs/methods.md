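# Methods

This note records the models implemented in `flysim`, the assumptions
behind them, the parameters that matter, and the numerical choices that
were genuinely open. It documents what the code computes; every number
quoted here is produced by the test-suite or by `scripts/acceptance.py`.

## Units and conventions

Internal computation is SI (m, kg, s, rad, N). Bench units — cm, mg, ms,
degrees — appear only at the I/O boundary, through `flysim.units`. The
world frame is right-handed with +z up and gravity (0, 0, −9.81) m s⁻²;
the body frame has +x from thorax to head, +y to the fly's left, +z
dorsal. Quaternions are stored (w, x, y, z) and renormalized after every
update.

## Body model

The fly is an articulated tree of 67 rigid segments: 9 axial segments
(head, thorax, 7 abdominal), a 4-segment proboscis, 2 antennae, 2 wings,
2 halteres and six legs of 8 segments each (coxa, femur, tibia, four
tarsal segments, claw). Segment masses are the bench-measured per-part
values — head 0.15 mg, thorax 0.34 mg, abdomen 0.38 mg (tapered over its
7 segments), 0.0162 mg per leg, 0.008 mg per wing — summing to
0.983 mg. Proboscis, antennae and halteres carry negligible mass and are
assigned zero. Geometry (segment primitives and offsets) is a plausible
reconstruction consistent with the 0.297 cm body length and 0.604 cm
wing span; inertia tensors come from each geometric primitive under
uniform density.

Joints are built from up to three hinge axes (triples approximate ball
joints at the neck, wing base and body–coxa). The per-joint DoF layout
is a documented approximation — 85 internal hinge DoFs plus the 6-DoF
free root — exposed programmatically via `KinematicTree.joint_names()`
rather than hard-coded to any particular total, because printed
per-joint information does not determine a unique assignment. The
abdominal pitch chain and each leg's four tarsal joints are
tendon-coupled (one scalar drives the group). Variants: `flight` freezes
the leg DoFs (legs retracted), `walking` freezes the wings; both keep
all 67 segments and the full mass.

The rest pose q = 0 is the default standing pose and doubles as the IK
reference pose q₀.

## Quasi-steady fluid model

A stateless approximation assigning instantaneous forces and torques to
a rigid ellipsoid (semi-axes a, b, c) from its body-frame velocity v,
angular velocity ω, the fluid density ρ and viscosity β — no wake
memory. Five components, scaled by the dimensionless coefficient vector
`fluidcoef = (c_blunt, c_slender, c_angular, c_kutta, c_magnus)` with
default (1.0, 0.5, 1.5, 1.7, 1.0); the index mapping is a package
convention and each component reads its own named field, so a different
mapping is a one-line configuration change:

* **Viscous resistance** (low Reynolds, linear):
  F = −6πβ r_D v, T = −8πβ r_D³ ω with equivalent radius
  r_D = (a+b+c)/3. Exact Stokes drag and rotational Stokes drag in the
  sphere limit.
* **Quadratic drag**:
  F = −ρ|v| [c_blunt A_proj(v̂) + c_slender max(0, A_max − A_proj(v̂))] v,
  where A_proj(n̂) = π√(b²c²n₁² + a²c²n₂² + a²b²n₃²) is the silhouette
  area along the motion direction and A_max the largest cross-section;
  the slender term keeps edgewise (small-silhouette) motion dissipative.
  Angular: T_i = −ρ c_angular |ω| ω_i (8/15)π r_j r_k (r_j³ + r_k³),
  built from the two semi-axes orthogonal to axis i; the shape factor is
  a smooth, dimensionally consistent interpolation chosen by this
  package (the torque magnitude prefactor is not constrained by any of
  the limit checks, only its sign and scalings are).
* **Magnus lift**: F = c_magnus ρ V (ω × v), V = (4/3)πabc.
* **Kutta (circulation) lift**: with chord normal n̂ (unit vector of the
  smallest semi-axis), sin α = v̂·n̂ and u = n̂ − (v̂·n̂)v̂,
  F = c_kutta ρ A_max |v|² sin α · u. |F| follows the thin-wing
  sin α cos α law — zero edgewise and broadside, maximal at 45° — and F
  is perpendicular to v in the plane of v and n̂.
* **Added mass**: Lamb's potential-flow coefficients
  α_i = abc·(2/3)·R_D(r_j², r_k², r_i²) (Carlson symmetric integral,
  `scipy.special.elliprd`), translational virtual mass
  ρV α_i/(2−α_i) per axis (ρV/2 in the sphere limit, 8/3·ρR³ broadside
  in the thin-disc limit) and Lamb's rotational entries (zero for
  symmetric sections). The added-mass *force* applied during simulation
  is −M_A a with the translational block and the wing-centre
  acceleration obtained by finite differences across physics steps.

Verified limits: Stokes sphere, sphere and disc added mass, Kutta peak
at 45° on a 0.1° sweep, rotation equivariance to 1e−10 relative, mirror
antisymmetry of torques, and non-positive drag power on random states.

Default medium is air at 20 °C (ρ = 1.204 kg m⁻³, β = 1.8e−5 Pa·s),
configurable.

## Wing-beat pattern generator

A fixed, mirror-symmetric, periodic baseline of the six wing angles
(stroke/yaw, deviation/roll, pitch per wing) on a phase grid, replayed
with linear periodic interpolation. The mirror convention maps left to
right channels with signs (−1, −1, +1). The shipped synthetic hovering
pattern uses a ±70° sinusoidal stroke, a ±15° figure-of-eight deviation
(double frequency) and a ±45° pitch schedule that flips at each stroke
reversal; a recorded pattern can be loaded from CSV with channel
remapping.

A scalar command in [−1, 1] modulates the wing-beat frequency within a
10% band centred at 218 Hz, interpreted as ±5%: f = 218(1 + 0.05·u) Hz.
Because the pattern is parameterized by phase, frequency modulation only
changes the phase velocity; a commanded change ramps the frequency
linearly at a rate completing a full-band swing within one wing-beat
cycle, so the output angles are continuous through switches (no
per-frequency table resampling is needed). The phase accumulator uses
Kahan compensation, keeping the no-drift property at the 1e−12 level
over arbitrarily many steps.

## Flight simulator and calibration

One free rigid body (total mass 0.9832 mg from the body model, inertia
from the rest pose) carries two wing ellipsoids
(semi-axes 0.044 × 0.1285 × 0.0005 cm — chord, span, thickness) hinged
at the shoulders. Each wing has stroke, deviation and pitch hinges
driven by a position servo g(θ* − θ) − d·θ̇ acting against the wing's
hinge inertia (ellipsoid about its root, uniform density, 0.008 mg) and
the hinge-projected fluid torque. The wings' fluid wrenches, thorax
quadratic drag and gravity act on the body; wing-inertia back-reaction
on the body is omitted (wing mass is 1.6% of body mass). Integration is
semi-implicit Euler at the 0.05 ms physics step with control held
0.2 ms.

Two numerical choices matter at this step size. First, the linear servo
(spring and damper) is integrated backward-Euler; explicit integration
of a critically damped servo is unstable on the light pitch axis at any
useful gain. Second, the pattern target is evaluated at every physics
substep (at the end-of-substep time): a zero-order hold over the 0.2 ms
control step makes the wing motion jerky enough to corrupt the fluid
force traces.

**Servo tuning** doubles a single gain (shared by all three axes) from
an initial value I_max·(2πf)² until the mean absolute tracking error
over 5 cycles after a 2-cycle transient is below 5% of the per-channel
amplitude (the error is the max over channels of MAE/amplitude); at each
gain the damping is set critical per axis, d = 2√(I g), the smallest
damping avoiding underdamped wing oscillation. The procedure is
deterministic; the shipped conditions converge at ~4% MAE.

**Lift calibration** adjusts the Kutta coefficient by coordinate descent
— lift is linear in the coefficient at fixed kinematics, so each
iteration solves for the balancing value from the measured per-component
breakdown — until the cycle-averaged vertical fluid force over 6 wing
beats (body clamped in the hover posture) matches body weight to 5%.
The three drag coefficients stay fixed; the Magnus coefficient is only
touched if the Kutta update leaves its admissible range. The result is
re-verified on an independent rollout.

**Sensitivity**: varying the blunt-drag and Kutta coefficients by ±20%
changes the lift/weight ratio; a variant is flagged recoverable when the
ratio lies within [0.95², 1.05²], the band reachable by the ±5%
frequency command alone (lift scales with frequency squared).

With the calibrated coefficients, the cycle-averaged force-magnitude
budget during hover is led by Kutta lift and quadratic drag; viscous
resistance and Magnus are 14–160× smaller. The added-mass component sits
a factor ~8–10 below the two dominant terms — about one order of
magnitude, driven by the broadside added-mass reaction to the
double-frequency deviation plunge of the synthetic pattern. A recorded
wing trajectory with a gentler deviation channel would push this ratio
further down; the synthetic pattern is kept as specified rather than
adjusted to sharpen the separation.

## Contact and adhesion

Contacts obey an elliptic Coulomb cone (circular by default): slip iff
|f∥| > μ f⊥, half-angle atan(μ) = 45° at the default μ = 1. An adhesion
actuator with control in [0, 1] injects `control × max_force` along the
inward normal (default maximum: one body weight, 9.65e−6 N per leg); it
raises that contact's normal force by the injected amount without
changing the tangential force, enlarging the slip margin μf⊥ − |f∥| by
exactly μ·a, and summed over contacts it can hold the body on walls and
ceilings.

Static indeterminacy (more contacts than balance equations) is resolved
by the minimum-norm solution with non-negative normal components: all
contacts share one Lagrange multiplier λ with f∥ᵢ = Pᵢλ (tangent
projection) and f⊥ᵢ = max(0, n̂ᵢ·λ), found by active-set iteration; a
residual above 1e−9 N (pure tension without adhesion) is reported as
detachment. Adhesion engages only at geometrically active contacts
(gap ≤ 1e−6 m). This solver handles quasi-static scenarios; it is not a
dynamic frictional LCP.

## Walking reference-data preparation

Selection keeps maximal frame runs where (i) every neighbour fly is more
than one body length from the CoM proxy (thorax-keypoint centroid) and
(ii) the CoM velocity component along the body axis (thorax front minus
rear midpoint) exceeds the perpendicular component; runs shorter than 20
frames (133 ms at 150 fps) are dropped, as are runs whose mean
leg-tip/CoM speed ratio is ≥ 1.5. Durations count one camera period per
frame, so resampling a 20-frame snippet to the 2 ms control step yields
67 frames (values held past the last sample; endpoints preserved).

Swing/stance labelling thresholds the *signed forward* component of the
egocentric leg-tip velocity — in the fly's frame a stance tip drifts
backward at the walking speed while a swing tip shoots forward — with
hysteresis v_hi = 0.3, v_lo = 0.15 cm s⁻¹ (config-exposed; the printed
record does not fix them) and a 2-frame minimum phase duration. The
velocity uses a forward difference so a frame is labelled by the motion
in the interval it starts, matching the generator's frame-start phase
convention.

Lifting adds z: stance tips stay at z = 0; each swing maps its progress
to x ∈ [0, π] (midpoint-sampled, so an odd-length swing's middle frame
reaches exactly A) and traces z = A sin x with per-pair amplitudes
A = 0.086, 0.047, 0.051 cm for T1, T2, T3. Body keypoints sit at a fixed
height and pitch; the default height is the standing height of the body
model's rest pose (FK of q = 0). Joint velocities use central
differences (one-sided at the ends).

## Inverse kinematics

Objective: Σᵢ‖sᵢ(q) − sᵢ*‖² + λ‖q − q₀‖² over joint angles and
(optionally) the root pose, with λ = 1e−4 cm² rad⁻² (1e−8 SI) and
q₀ = 0. The descent direction comes from analytic geometric Jacobians
(hinge column a × (p − o)); each iterate solves the Levenberg-damped
system (JᵀJ + λI + μD)Δ = −g, raising μ (×4) until the objective
decreases and relaxing it (÷3) after acceptance — the large-μ limit is
plain gradient descent, and the damping plays the role of the
backtracking line search while curing the severe metre/radian
ill-conditioning that makes undamped first-order steps impractically
slow on this model. Joint limits are enforced by projection after every
accepted step; the objective is non-increasing across accepted
iterations; stopping at relative decrease < 1e−8, objective < 1e−24 m²,
or 500 iterations. Trajectories warm-start each frame from the previous
fit; whole-body fits co-optimize the root pose (joint, not sequential).
Single-leg fits hold the root fixed, optionally rescaling the leg's
segment lengths to the targets' inter-keypoint distances first (the
tarsal chain shares one factor), which decouples animal size from DoF
mismatch.

On FK-generated targets the fit recovers keypoints to machine precision
(λ = 0) and to well under 1% of body length with the default λ.

## Gait and flight statistics

Tracking error: Euclidean CoM distance and geodesic quaternion angle
2·acos(|⟨q₁,q₂⟩|) per frame, summarized by median and quartiles.
Stance counts: per-snippet mean of simultaneous stance legs, binned by
snippet mean speed (0.25 cm s⁻¹ bins over [0, 4] cm s⁻¹); a duty-d gait
gives 6d. Swing-onset phases: onsets mapped into the enclosing cycle of
the reference leg (L1) as angles in [0, 2π); the circular median is the
observed angle minimizing mean absolute arc distance, ties broken by the
smallest angle — invariant (equivariant) under rotation of the phase
origin. Turn asymmetry: mean left-minus-right egocentric swing
displacement; for the generator this equals duty × stride difference, so
a 20% inside-stride reduction is recovered with its sign flipping under
turn reversal. Saccade profiles align trajectories at the unique peak of
|linear acceleration| and report median/quartile traces of speed,
relative heading and body angular velocity; flat-acceleration
trajectories are excluded with a warning. Wing beats are segmented at
stroke maxima and split steady/unsteady by per-beat mean |body
acceleration| against a threshold defaulting to the dataset median
(config-exposed; not fixed by any printed value).

## Imitation-environment contracts and vision world

Steering commands are egocentric: Δposition = R(q_t)ᵀ(p_{t+dt} − p_t)
and the axis-angle of q_t⁻¹q_{t+dt} per control step; integrating the
commands along a reference trajectory reconstructs its final pose to
first order. The imitation reward is a product of Gaussian kernels
exp(−e²/2σ²) over CoM, orientation and mean keypoint errors with
σ_com = σ_kp = 0.05 cm and σ_ori = 10° (defaults; the functional form
is the package's choice and all widths are config-exposed). Episodes
end as `failure` (terrain contact or tracking blow-up; no value
bootstrap) or `time_limit` (bootstrap).

Bump obstacles are raised cosines z(x) = (h/2)(1 − cos 2πx/L) with
h ~ U[0, 2] cm and L ~ U[2, 4] cm, giving max inclination
atan(πh/L) ≤ 72°; sampling is bit-reproducible from the seed. The
trench is a sine-shaped corridor (amplitude 1 cm, period 10 cm, width
and depth 1 cm by default — the corridor dimensions are package
defaults) sunk into level ground; collision tests the lateral offset
from the centreline and the depth bounds. Two head-fixed pinhole eye
cameras (32 × 32 pixels, 150° FOV, yawed ±30°) ray-march the terrain
heightfield and shade each pixel by 1/(1 + distance) with 0 for sky —
a depth encoding, chosen over luminance as the simplest deterministic
signal that makes walls and ground distance visible at this resolution.
Policy actions in [−1, 1] map affinely onto actuator ranges (exact
round-trip inverse).

## Synthetic generators: what they emulate and what they do not

The walking generator produces a kinematically consistent 13-keypoint
arena track at 150 fps: body keypoints advected along a straight or
circular path at the commanded speed, leg tips pinned to the world in
stance and advancing one stride per cycle in swing, tripod phasing
(L1/R2/L3 against R1/L2/R3), duty factor exact in the ground truth. The
defaults — 2 cm s⁻¹, duty 0.5, 7.5 steps/s — sit mid-range for arena
walking speeds of 0–4 cm s⁻¹; the 7.5 Hz cadence makes every gait
transition land on a camera frame boundary so ground-truth labels carry
no discretization ambiguity, and the swing advance is linear so the
egocentric forward velocity switches crisply. Real tracks differ in ways
the generator deliberately omits: tracking noise (available as optional
jitter but off by default), inter-stride variability, curved
within-swing paths, body yaw oscillation, and non-tripod coordination at
low speeds. Passing the recovery tests therefore shows the pipeline is
correct on clean tripod kinematics, not that its thresholds are optimal
on noisy video.

The flight generator emits CoM + quaternion trajectories at the 0.2 ms
control step: straight cruising (up to the ~30 cm s⁻¹ range), hover, and
a saccade template whose heading follows a tanh step (smooth, single
acceleration peak) — sufficient for the alignment and steering
contracts, but with none of the wing-beat-scale body oscillation of real
flight. Mirror augmentation reflects across the vertical xz-plane:
positions (x, −y, z), quaternions (w, −x, y, −z) (the conjugation
M R M, M = diag(1, −1, 1)); applied twice it is the identity, bit-exact.

## Problem sizes

Default test and script workloads are sized for a laptop core: servo
tuning replays ~7 cycles per gain over ~13 gain doublings (≈10 s), lift
calibration converges in ≤3 iterations (≈2 s), hover analyses use 5–10
cycles, IK recovery uses 10–20 random frames, and walking fixtures are
2–3 s of track. All stochastic paths take explicit seeds.

## Known limitations

* The fluid model is quasi-steady: no wake, no leading-edge-vortex
  dynamics, no wing flexibility; coefficients absorb these effects.
* Wing inertia does not back-react on the body; hover rollouts with a
  free body drift and are reported, not asserted.
* The contact solver is static; it does not replace a dynamic
  constraint solver for walking simulation.
* The default body geometry is a plausible reconstruction, not a
  measured one; only the printed masses, counts and lengths are
  authoritative.
* The added-mass/dominant-force separation during hover is sensitive to
  the baseline pattern's deviation channel (see the flight section).
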