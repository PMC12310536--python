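"""Desk-scale rigid-body flight simulator.

One free rigid body (the fly, 0.983 mg) carries two servo-driven slender
wing ellipsoids.  Each wing has three hinge DoFs at the shoulder — stroke
(yaw, about the body z axis), deviation (roll, about x) and pitch (about
the span axis y) — driven by position servos with torque
``g (target - angle) - d * rate`` against the wing's hinge inertia and
the quasi-steady fluid load.  The fluid wrench of each wing, thorax drag
and gravity act on the body; wing-inertia back-coupling onto the body is
deliberately omitted (wing mass is 1.6% of body mass).  Integration is
semi-implicit Euler at a 0.05 ms physics step with control held for
0.2 ms.

The two calibration procedures mirror the standard workflow: (1) the wing
servo gain is doubled until the mean absolute tracking error falls below
5% of the wing-angle amplitude, with damping set critical at each step to
avoid underdamping; (2) the Kutta-lift coefficient is adjusted by
coordinate descent until cycle-averaged net lift balances body weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from flysim import units
from flysim.body import build_default_fly
from flysim.fluid import (
    AIR,
    BodyKinematics,
    EllipsoidGeom,
    FluidCoefficients,
    FluidMedium,
    Wrench,
    quadratic_drag_wrench,
    total_fluid_wrench,
    viscous_resistance_wrench,
)
from flysim.rotations import (
    IDENTITY_QUAT,
    quat_conj,
    quat_integrate,
    quat_mul,
    quat_normalize,
    quat_rotate,
    quat_to_matrix,
    matrix_to_quat,
)
from flysim.wpg import WingBeatPattern

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class SimClock:
    """Physics and control step sizes; control must be a multiple."""

    physics_dt: float = 5e-5
    control_dt: float = 2e-4

    def __post_init__(self):
        n = self.control_dt / self.physics_dt
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("control_dt must be an integer multiple of physics_dt")

    @property
    def substeps(self) -> int:
        return int(round(self.control_dt / self.physics_dt))


@dataclass
class WingServo:
    """Per-axis servo gain (N m rad^-1), damping (N m s rad^-1), torque cap."""

    gain: np.ndarray
    damping: np.ndarray
    torque_limit: float = np.inf

    def __post_init__(self):
        self.gain = np.broadcast_to(np.asarray(self.gain, dtype=float), (3,)).copy()
        self.damping = np.broadcast_to(
            np.asarray(self.damping, dtype=float), (3,)
        ).copy()
        if np.any(self.gain < 0) or np.any(self.damping < 0):
            raise ValueError("servo gain and damping must be >= 0")


@dataclass
class FlightState:
    """Free-body state plus the six wing joint angles and rates."""

    time: float = 0.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: IDENTITY_QUAT.copy())
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # world
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))  # body frame
    wing_angles: np.ndarray = field(default_factory=lambda: np.zeros(6))
    wing_rates: np.ndarray = field(default_factory=lambda: np.zeros(6))
    # previous world-frame wing-centre velocities, for added-mass accel
    wing_center_vel: np.ndarray = field(default_factory=lambda: np.zeros((2, 3)))

    def __post_init__(self):
        for name in ("position", "velocity", "omega"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.orientation = quat_normalize(self.orientation)
        self.wing_angles = np.asarray(self.wing_angles, dtype=float)
        self.wing_rates = np.asarray(self.wing_rates, dtype=float)
        self.wing_center_vel = np.asarray(self.wing_center_vel, dtype=float)


def _rot_z(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_x(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


class FlightSimulator:
    """Body + two servo-driven wing ellipsoids under quasi-steady fluid."""

    #: wing ellipsoid semi-axes (chord, span, thickness), m
    WING_SEMI_AXES = (4.4e-4, 1.285e-3, 5e-6)
    #: shoulder (hinge) offsets in the body frame, m: left, right
    SHOULDER = (np.array([5e-5, 4.5e-4, 3.5e-4]), np.array([5e-5, -4.5e-4, 3.5e-4]))
    #: thorax drag ellipsoid semi-axes, m
    THORAX_SEMI_AXES = (5.5e-4, 4.5e-4, 4.5e-4)

    def __init__(
        self,
        servo: WingServo | None = None,
        coeffs: FluidCoefficients | None = None,
        medium: FluidMedium = AIR,
        clock: SimClock | None = None,
        gravity: float = units.GRAVITY,
        body_drag: bool = True,
    ):
        self.servo = servo if servo is not None else WingServo(1e-6, 1e-9)
        self.coeffs = coeffs if coeffs is not None else FluidCoefficients()
        self.medium = medium
        self.clock = clock if clock is not None else SimClock()
        self.gravity = gravity
        self.body_drag = body_drag

        tree = build_default_fly("flight")
        self.mass = tree.total_mass()
        # body rotational inertia: segment geoms, uniform density, rest pose
        from flysim.body import forward_kinematics, com as tree_com

        pose = tree.zero_pose()
        frames, _ = forward_kinematics(tree, pose)
        c = tree_com(tree, pose)
        inertia = np.zeros((3, 3))
        for s in tree.segments:
            p, q = frames[s.name]
            rot = quat_to_matrix(q)
            i_local = rot @ s.geom.inertia(s.mass) @ rot.T
            d = p - c
            inertia += i_local + s.mass * ((d @ d) * np.eye(3) - np.outer(d, d))
        self.body_inertia = inertia
        self._body_inertia_inv = np.linalg.inv(inertia)

        # wing hinge inertias about (stroke, deviation, pitch); ellipsoid
        # about its root, uniform density over the wing mass
        m_w = units.mg_to_kg(0.008)
        a, b, c_ = self.WING_SEMI_AXES
        i_cm = np.array(
            [m_w / 5 * (b * b + c_ * c_),  # about chord x
             m_w / 5 * (a * a + c_ * c_),  # about span y
             m_w / 5 * (a * a + b * b)]    # about normal z
        )
        # hinge at the root: parallel-axis along span for stroke & normal axes
        self.wing_inertia = np.array(
            [i_cm[0] + m_w * b * b, i_cm[1], i_cm[2] + m_w * b * b]
        )[[2, 0, 1]]  # reorder to (stroke about z, deviation about x, pitch about y)
        self.weight = self.mass * self.gravity

    # -- wing geometry ---------------------------------------------------

    def _wing_frames(self, angles, rates):
        """Per-wing (rotation, hinge axes, omega, centre offset, centre vel).

        Everything in the body frame; ``angles``/``rates`` are the 6-vector
        (yaw_L, roll_L, pitch_L, yaw_R, roll_R, pitch_R).
        """
        out = []
        span = self.WING_SEMI_AXES[1]
        for w, sign in ((0, 1.0), (1, -1.0)):
            yaw, roll, pitch = angles[3 * w : 3 * w + 3]
            dyaw, droll, dpitch = rates[3 * w : 3 * w + 3]
            rz, rx, ry = _rot_z(yaw), _rot_x(roll), _rot_y(pitch)
            rot = rz @ rx @ ry
            ax_yaw = np.array([0.0, 0, 1])
            ax_roll = rz @ np.array([1.0, 0, 0])
            ax_pitch = rz @ rx @ np.array([0.0, 1, 0])
            omega = dyaw * ax_yaw + droll * ax_roll + dpitch * ax_pitch
            r_off = rot @ np.array([0.0, sign * span, 0.0])
            v_center = np.cross(omega, r_off)
            out.append((rot, (ax_yaw, ax_roll, ax_pitch), omega, r_off, v_center))
        return out

    def wing_fluid(self, state: FlightState, collect=False):
        """Fluid wrenches of both wings.

        Returns ``(net_force_world, net_torque_world_about_root,
        hinge_torques (6,), breakdowns)`` where ``breakdowns`` is a list of
        two dicts (world-frame per-component wrenches) when ``collect``.
        """
        q = state.orientation
        rot_body = quat_to_matrix(q)
        frames = self._wing_frames(state.wing_angles, state.wing_rates)
        f_net = np.zeros(3)
        t_net = np.zeros(3)
        hinge = np.zeros(6)
        breakdowns = []
        new_center_vel = np.zeros((2, 3))
        for w, (rot, axes, omega_b, r_off, v_c_b) in enumerate(frames):
            p_hinge_b = self.SHOULDER[w]
            p_center_b = p_hinge_b + r_off
            # world kinematics of the wing centre
            v_world = (
                state.velocity
                + rot_body @ (np.cross(state.omega, p_center_b) + v_c_b)
            )
            w_world = rot_body @ (state.omega + omega_b)
            new_center_vel[w] = v_world
            a_world = (v_world - state.wing_center_vel[w]) / self.clock.physics_dt
            quat_wing = quat_mul(q, matrix_to_quat(rot))
            geom = EllipsoidGeom(
                self.WING_SEMI_AXES, span_axis=1,
                pose_pos=np.zeros(3), pose_quat=quat_wing,
            )
            q_inv = quat_conj(quat_wing)
            kin = BodyKinematics(
                v=quat_rotate(q_inv, v_world),
                w=quat_rotate(q_inv, w_world),
                a_lin=quat_rotate(q_inv, a_world),
            )
            local, bd = total_fluid_wrench(geom, kin, self.medium, self.coeffs)
            force = quat_rotate(quat_wing, local.force)
            torque = quat_rotate(quat_wing, local.torque)
            f_net += force
            arm_world = rot_body @ p_center_b
            t_net += np.cross(arm_world, force) + torque
            # hinge-projected load torque (about the shoulder)
            t_hinge_w = torque + np.cross(rot_body @ r_off, force)
            for k, ax in enumerate(axes):
                hinge[3 * w + k] = float((rot_body @ ax) @ t_hinge_w)
            if collect:
                breakdowns.append(
                    {
                        name: Wrench(
                            quat_rotate(quat_wing, wr.force),
                            quat_rotate(quat_wing, wr.torque),
                        )
                        for name, wr in bd.items()
                    }
                )
        return f_net, t_net, hinge, breakdowns, new_center_vel

    # -- stepping --------------------------------------------------------

    def step(
        self,
        state: FlightState,
        wing_targets=None,
        wing_torques=None,
        fluid: bool = True,
        fixed_body: bool = False,
        collect_forces: bool = False,
    ) -> FlightState:
        """Advance one control step (physics substeps inside).

        ``wing_targets`` (6,) drives the wing servos; ``wing_torques``
        applies direct hinge torques instead.  ``fixed_body`` clamps the
        root (used by the calibration procedures).  With
        ``collect_forces`` the return value is ``(state, info)`` where
        ``info`` carries the substep-averaged net fluid force, the
        instantaneous final-substep force and its per-wing component
        breakdown.
        """
        s = replace(
            state,
            position=state.position.copy(),
            velocity=state.velocity.copy(),
            omega=state.omega.copy(),
            wing_angles=state.wing_angles.copy(),
            wing_rates=state.wing_rates.copy(),
            wing_center_vel=state.wing_center_vel.copy(),
        )
        dt = self.clock.physics_dt
        gains = np.concatenate([self.servo.gain, self.servo.gain])
        damps = np.concatenate([self.servo.damping, self.servo.damping])
        inertia6 = np.concatenate([self.wing_inertia, self.wing_inertia])
        force_accum = np.zeros(3)
        info = {"force_mean": np.zeros(3), "force": np.zeros(3), "breakdown": None}
        for sub in range(self.clock.substeps):
            last = sub == self.clock.substeps - 1
            if fluid:
                f_fluid, t_fluid, hinge, bd, new_cv = self.wing_fluid(
                    s, collect=collect_forces and last
                )
                force_accum += f_fluid
                if collect_forces and last:
                    info["force"] = f_fluid.copy()
                    info["breakdown"] = bd
            else:
                f_fluid = np.zeros(3)
                t_fluid = np.zeros(3)
                hinge = np.zeros(6)
                new_cv = s.wing_center_vel
            # wing joint dynamics; the linear servo (spring + damper) is
            # integrated backward-Euler so stiff gains on the light wing
            # hinges stay unconditionally stable:
            #   w' (1 + (d dt + g dt^2)/I) = w + dt (g err + tau_ext)/I
            if wing_torques is not None:
                tau = np.asarray(wing_torques, dtype=float) + hinge
                s.wing_rates = s.wing_rates + tau / inertia6 * dt
            elif wing_targets is not None:
                # callable targets are re-evaluated at every physics substep
                # (the pattern generator outputs angles each simulation step);
                # the target is the desired angle at the end of the substep
                tgt = (
                    wing_targets(s.time + dt)
                    if callable(wing_targets)
                    else wing_targets
                )
                err = np.asarray(tgt, dtype=float) - s.wing_angles
                spring = np.clip(gains * err, -self.servo.torque_limit,
                                 self.servo.torque_limit)
                denom = 1.0 + (damps * dt + gains * dt * dt) / inertia6
                s.wing_rates = (
                    s.wing_rates + (spring + hinge) / inertia6 * dt
                ) / denom
            else:
                s.wing_rates = s.wing_rates + hinge / inertia6 * dt
            s.wing_angles = s.wing_angles + s.wing_rates * dt
            # body dynamics
            if not fixed_body:
                force = f_fluid + np.array([0.0, 0, -self.weight])
                if self.body_drag and fluid:
                    geom = EllipsoidGeom(self.THORAX_SEMI_AXES,
                                         pose_quat=s.orientation)
                    q_inv = quat_conj(s.orientation)
                    kin = BodyKinematics(
                        v=quat_rotate(q_inv, s.velocity), w=s.omega
                    )
                    drag = quadratic_drag_wrench(geom, kin, self.medium, self.coeffs)
                    visc = viscous_resistance_wrench(geom, kin, self.medium)
                    force = force + quat_rotate(s.orientation,
                                                drag.force + visc.force)
                    t_fluid = t_fluid + quat_rotate(
                        s.orientation, drag.torque + visc.torque
                    )
                torque_body = quat_rotate(quat_conj(s.orientation), t_fluid)
                s.velocity = s.velocity + force / self.mass * dt
                s.position = s.position + s.velocity * dt
                iw = self.body_inertia @ s.omega
                dom = self._body_inertia_inv @ (
                    torque_body - np.cross(s.omega, iw)
                )
                s.omega = s.omega + dom * dt
                s.orientation = quat_integrate(s.orientation, s.omega, dt)
            s.wing_center_vel = new_cv
            s.time += dt
        if not np.all(
            np.isfinite(np.concatenate([s.position, s.velocity, s.omega,
                                        s.wing_angles, s.wing_rates]))
        ):
            raise SimulationError(
                f"non-finite state at t={s.time:.6f}s: pos={s.position}, "
                f"vel={s.velocity}, wings={s.wing_angles}"
            )
        if collect_forces:
            info["force_mean"] = force_accum / self.clock.substeps
            return s, info
        return s


# ---------------------------------------------------------------------------
# calibration procedures
# ---------------------------------------------------------------------------

def _replay(
    sim: FlightSimulator,
    pattern: WingBeatPattern,
    n_cycles: float,
    fluid: bool = True,
    collect_forces: bool = False,
    fixed_body: bool = True,
    state: FlightState | None = None,
):
    """Drive the wings with pattern targets; body fixed unless requested.

    Returns a dict of recorded per-control-step arrays.
    """
    freq = pattern.base_frequency
    clock = sim.clock
    n_steps = int(round(n_cycles / freq / clock.control_dt))
    if state is None:
        state = FlightState(wing_angles=pattern.sample(0.0))
    rec = {
        "time": np.zeros(n_steps),
        "targets": np.zeros((n_steps, 6)),
        "angles": np.zeros((n_steps, 6)),
        "position": np.zeros((n_steps, 3)),
        "orientation": np.zeros((n_steps, 4)),
        "fluid_force": np.zeros((n_steps, 3)),
        "breakdown": [] if collect_forces else None,
    }
    target_fn = lambda t: pattern.sample((t * freq) % 1.0)
    for i in range(n_steps):
        state, info = sim.step(state, wing_targets=target_fn, fluid=fluid,
                               fixed_body=fixed_body, collect_forces=True)
        rec["time"][i] = state.time
        rec["targets"][i] = pattern.sample((state.time * freq) % 1.0)
        rec["angles"][i] = state.wing_angles
        rec["position"][i] = state.position
        rec["orientation"][i] = state.orientation
        rec["fluid_force"][i] = info["force_mean"]
        if collect_forces:
            rec["breakdown"].append(info["breakdown"])
    rec["state"] = state
    return rec


def tracking_mae(rec, pattern: WingBeatPattern, skip_cycles: float = 2.0):
    """Max over channels of MAE / amplitude after the transient."""
    freq = pattern.base_frequency
    t0 = skip_cycles / freq
    mask = rec["time"] > rec["time"][0] + t0
    err = np.abs(rec["angles"][mask] - rec["targets"][mask]).mean(axis=0)
    amp = pattern.amplitude()
    amp = np.where(amp > 0, amp, 1.0)
    return float(np.max(err / amp))


def tune_wing_actuator(
    pattern: WingBeatPattern,
    tolerance: float = 0.05,
    sim: FlightSimulator | None = None,
    n_cycles: float = 5.0,
    max_iter: int = 24,
    initial_gain: float | None = None,
) -> WingServo:
    """Increase servo gain until MAE < tolerance x amplitude.

    The same gain is used for all three wing axes.  At each gain the
    damping is set critical per axis, ``d = 2 sqrt(I g)``, which is the
    smallest damping that avoids underdamped wing oscillation.
    Deterministic given the same pattern and settings.
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if sim is None:
        sim = FlightSimulator()
    if np.max(pattern.amplitude()) == 0.0:
        gain = initial_gain if initial_gain else 1e-9
        return WingServo(gain, 2.0 * np.sqrt(sim.wing_inertia * gain))
    omega_drive = 2 * np.pi * pattern.base_frequency
    gain = (
        initial_gain
        if initial_gain is not None
        else float(np.max(sim.wing_inertia)) * omega_drive**2
    )
    best = (np.inf, None)
    for _ in range(max_iter):
        servo = WingServo(gain, 2.0 * np.sqrt(sim.wing_inertia * gain))
        trial = FlightSimulator(
            servo=servo, coeffs=sim.coeffs, medium=sim.medium,
            clock=sim.clock, gravity=sim.gravity, body_drag=sim.body_drag,
        )
        rec = _replay(trial, pattern, n_cycles + 2, fixed_body=True)
        mae = tracking_mae(rec, pattern)
        logger.info("gain %.3e -> MAE/amplitude %.4f", gain, mae)
        if mae < best[0]:
            best = (mae, servo)
        if mae < tolerance:
            return servo
        gain *= 2.0
    raise CalibrationError(
        f"servo tuning did not reach MAE < {tolerance:.2%}; best {best[0]:.2%}"
    )


def mean_lift(
    sim: FlightSimulator, pattern: WingBeatPattern, n_cycles: float = 6.0,
    skip_cycles: float = 2.0,
):
    """Cycle-averaged world-frame vertical fluid force and its breakdown."""
    rec = _replay(sim, pattern, n_cycles + skip_cycles,
                  collect_forces=True, fixed_body=True)
    freq = pattern.base_frequency
    mask = rec["time"] > rec["time"][0] + skip_cycles / freq
    total = rec["fluid_force"][mask, 2].mean()
    comp_z = {}
    for name in ("viscous_resistance", "quadratic_drag", "magnus", "kutta",
                 "added_mass"):
        vals = [
            sum(bd[w][name].force[2] for w in range(2))
            for bd, m in zip(rec["breakdown"], mask)
            if m
        ]
        comp_z[name] = float(np.mean(vals))
    return float(total), comp_z


def calibrate_fluidcoef(
    initial: FluidCoefficients,
    pattern: WingBeatPattern,
    servo: WingServo,
    tolerance: float = 0.05,
    max_iter: int = 10,
    medium: FluidMedium = AIR,
    clock: SimClock | None = None,
) -> FluidCoefficients:
    """Scale the lift coefficients until mean lift balances body weight.

    Coordinate descent on the Kutta coefficient (the dominant lift term),
    with the three drag coefficients held fixed; the Magnus coefficient is
    only touched if the Kutta update would leave the admissible range.
    """
    coeffs = FluidCoefficients.from_array(initial.as_array())
    best = (np.inf, coeffs)
    for it in range(max_iter):
        sim = FlightSimulator(servo=servo, coeffs=coeffs, medium=medium,
                              clock=clock)
        lift, comp = mean_lift(sim, pattern)
        resid = abs(lift - sim.weight) / sim.weight
        logger.info("calibration iter %d: lift/weight %.4f", it, lift / sim.weight)
        if resid < best[0]:
            best = (resid, coeffs)
        if resid < tolerance:
            return coeffs
        kutta_z = comp["kutta"]
        if abs(kutta_z) > 1e-16 and coeffs.kutta_lift > 0:
            # lift is linear in the coefficient at fixed kinematics
            new_k = coeffs.kutta_lift + (sim.weight - lift) * (
                coeffs.kutta_lift / kutta_z
            )
            new_k = float(np.clip(new_k, 0.05 * coeffs.kutta_lift,
                                  20.0 * coeffs.kutta_lift))
            coeffs = replace(coeffs, kutta_lift=new_k)
        else:
            magnus_z = comp["magnus"]
            if abs(magnus_z) < 1e-16:
                break
            new_m = coeffs.magnus_lift + (sim.weight - lift) * (
                coeffs.magnus_lift / magnus_z
            )
            coeffs = replace(coeffs, magnus_lift=max(new_m, 0.0))
    raise CalibrationError(
        f"lift calibration residual {best[0]:.2%} after {max_iter} iterations"
    )


def sensitivity_scan(
    coeffs: FluidCoefficients,
    pattern: WingBeatPattern,
    servo: WingServo,
    deltas=(-0.2, 0.0, 0.2),
    which=("blunt_drag", "kutta_lift"),
    medium: FluidMedium = AIR,
    clock: SimClock | None = None,
) -> pd.DataFrame:
    """Lift/weight ratio under per-coefficient variations.

    A variant is flagged successful when the ratio can be brought back to
    1 by the +-5% wing-beat-frequency command alone (lift scales with the
    square of frequency, so the recoverable band is [0.95^2, 1.05^2]).
    """
    rows = []
    for name in which:
        for d in deltas:
            c = replace(coeffs, **{name: getattr(coeffs, name) * (1 + d)})
            sim = FlightSimulator(servo=servo, coeffs=c, medium=medium,
                                  clock=clock)
            lift, _ = mean_lift(sim, pattern)
            ratio = lift / sim.weight
            rows.append(
                {
                    "coefficient": name,
                    "delta": d,
                    "lift_weight_ratio": ratio,
                    "success": bool(0.95**2 <= ratio <= 1.05**2),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class HoverResult:
    trajectory: pd.DataFrame  # t_ms, x_cm..z_cm, qw..qz
    forces: pd.DataFrame  # t_ms, wing, component, fx..tz (N, N m)

    def mean_component_magnitudes(self) -> dict:
        """Cycle-averaged |force| per fluid component, both wings pooled."""
        f = self.forces
        mag = np.linalg.norm(f[["fx", "fy", "fz"]].to_numpy(), axis=1)
        out = {}
        for name in f["component"].unique():
            out[name] = float(mag[f["component"] == name].mean())
        return out


def hover_rollout(
    pattern: WingBeatPattern,
    servo: WingServo,
    coeffs: FluidCoefficients,
    n_cycles: float = 10.0,
    free_body: bool = False,
    medium: FluidMedium = AIR,
    clock: SimClock | None = None,
) -> HoverResult:
    """Replay the pattern and record per-component fluid force traces."""
    sim = FlightSimulator(servo=servo, coeffs=coeffs, medium=medium, clock=clock)
    rec = _replay(sim, pattern, n_cycles, collect_forces=True,
                  fixed_body=not free_body)
    traj = pd.DataFrame(
        {
            "t_ms": units.s_to_ms(rec["time"]),
            "x_cm": units.m_to_cm(rec["position"][:, 0]),
            "y_cm": units.m_to_cm(rec["position"][:, 1]),
            "z_cm": units.m_to_cm(rec["position"][:, 2]),
            "qw": rec["orientation"][:, 0],
            "qx": rec["orientation"][:, 1],
            "qy": rec["orientation"][:, 2],
            "qz": rec["orientation"][:, 3],
        }
    )
    rows = []
    for t, bd in zip(rec["time"], rec["breakdown"]):
        for w, side in enumerate("LR"):
            for name, wr in bd[w].items():
                rows.append(
                    {
                        "t_ms": units.s_to_ms(t),
                        "wing": side,
                        "component": name,
                        "fx": wr.force[0], "fy": wr.force[1], "fz": wr.force[2],
                        "tx": wr.torque[0], "ty": wr.torque[1],
                        "tz": wr.torque[2],
                    }
                )
    return HoverResult(traj, pd.DataFrame(rows))
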