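"""Synthetic fixture generators for walking tracks and flight trajectories.

These generators stand in for recorded arena and flight datasets: they
produce kinematically consistent data with known ground truth (speeds,
duty factors, swing phases, acceleration peaks), which every downstream
statistic can be checked against.  All randomness is seeded.

Walking: a hexapod advancing at a commanded speed with a tripod gait —
legs L1/R2/L3 share one phase, R1/L2/R3 the antiphase.  During stance a
leg tip is pinned to the world; during swing it advances by one stride
in the walking direction along a smooth profile.  Output is a 13-keypoint
2D track at 150 fps in cm, like the arena data.

Flight: CoM + quaternion trajectories at the 0.2 ms flight control step;
templates are straight cruising, hover, and a saccade (a smooth rapid yaw
turn with a single acceleration peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flysim.rotations import quat_from_axis_angle, quat_mul, quat_normalize
from flysim.walking import LEG_ORDER, RawArenaTrack

FLIGHT_CONTROL_DT = 2e-4  # s

#: egocentric home positions of the six leg tips, cm (x forward, y left)
LEG_HOME_CM = {
    "T1_L": (0.12, 0.10), "T1_R": (0.12, -0.10),
    "T2_L": (0.0, 0.13), "T2_R": (0.0, -0.13),
    "T3_L": (-0.12, 0.11), "T3_R": (-0.12, -0.11),
}
#: tripod phases: L1/R2/L3 together, R1/L2/R3 in antiphase
TRIPOD_PHASE = {"T1_L": 0.0, "T2_R": 0.0, "T3_L": 0.0,
                "T1_R": 0.5, "T2_L": 0.5, "T3_R": 0.5}

#: egocentric body keypoints, cm: 3 head, 3 thorax, abdomen tip
BODY_KEYPOINTS_CM = np.array(
    [
        [0.12, 0.0], [0.10, 0.03], [0.10, -0.03],
        [0.055, 0.0], [0.0, 0.045], [0.0, -0.045],
        [-0.16, 0.0],
    ]
)


@dataclass
class SynthWalkParams:
    """Study conditions of the synthetic walker.

    Defaults emulate a fly walking at 2 cm/s with a duty-0.5 tripod gait
    at 7.5 steps/s (stride 0.27 cm), mid-range for arena speeds of
    0–4 cm/s; at 150 fps a 7.5 Hz cadence puts every gait transition on
    a frame boundary, keeping the ground-truth labels exact.
    """

    speed: float = 2.0  # cm/s
    turn_radius: float = np.inf  # cm; +left turn, inf = straight
    duty_factor: float = 0.5
    cadence: float = 7.5  # step cycles per second
    duration: float = 2.0  # s
    body_length: float = 0.297  # cm
    neighbor_distance: float = 3.0  # cm; body lengths away from the path
    lateral_noise: float = 0.0  # cm, optional keypoint jitter
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty factor must be in (0, 1)")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class SynthWalkResult:
    track: RawArenaTrack
    swing: np.ndarray  # (n, 6) ground-truth swing labels
    com_speed: np.ndarray  # (n,) cm/s
    heading: np.ndarray  # (n,) rad
    params: SynthWalkParams


def _swing_profile(u: np.ndarray) -> np.ndarray:
    """Swing advance profile: linear (constant protraction speed), so the
    egocentric forward velocity switches crisply at lift-off/touch-down."""
    return np.asarray(u, dtype=float)


def synth_walk_track(params: SynthWalkParams) -> SynthWalkResult:
    """Generate a tripod-gait 13-keypoint arena track with ground truth."""
    rng = np.random.default_rng(params.seed)
    fps = 150.0
    dt = 1.0 / fps
    n = int(round(params.duration * fps))
    ts = np.arange(n) * dt

    # CoM path: straight line or arc at the commanded speed
    if np.isinf(params.turn_radius):
        heading = np.zeros(n)
        com = np.stack([params.speed * ts, np.zeros(n)], axis=1)
    else:
        omega = params.speed / params.turn_radius
        heading = omega * ts
        r = params.turn_radius
        com = np.stack([r * np.sin(heading), r * (1 - np.cos(heading))], axis=1)

    cos_h, sin_h = np.cos(heading), np.sin(heading)

    def to_world(frame_idx, ego):
        c, s = cos_h[frame_idx], sin_h[frame_idx]
        rot = np.array([[c, -s], [s, c]])
        return com[frame_idx] + rot @ np.asarray(ego)

    kp = np.zeros((n, 13, 2))
    for i in range(n):
        c, s = cos_h[i], sin_h[i]
        rot = np.array([[c, -s], [s, c]])
        kp[i, :7] = com[i] + BODY_KEYPOINTS_CM @ rot.T

    stride = params.speed / params.cadence if params.cadence > 0 else 0.0
    swing = np.zeros((n, 6), dtype=bool)
    duty = params.duty_factor

    # exact phase bookkeeping: when the cadence divides the frame rate the
    # phase is rational in the frame index, so gait transitions land on
    # frame boundaries without floating-point jitter
    fpc = fps / params.cadence if params.cadence > 0 else np.inf
    exact = np.isfinite(fpc) and abs(fpc - round(fpc)) < 1e-9

    def phase_of(i: int, phase0: float) -> float:
        if exact:
            m = int(round(fpc))
            return ((i + int(round(phase0 * m))) % m) / m
        return (params.cadence * ts[i] + phase0) % 1.0

    for leg_idx, leg in enumerate(LEG_ORDER):
        home = np.array(LEG_HOME_CM[leg])
        phase0 = TRIPOD_PHASE[leg]
        # per-leg stride scaling for turning: inside legs step shorter
        if np.isinf(params.turn_radius):
            leg_stride = stride
        else:
            leg_stride = stride * (1.0 - home[1] / params.turn_radius)
        if params.speed == 0:
            for i in range(n):
                kp[i, 7 + leg_idx] = to_world(i, home)
            continue
        # cycle phase in [0,1): stance for [0, duty), swing for [duty, 1)
        anchor_frame = 0
        anchor = to_world(0, home + [leg_stride * duty / 2, 0])
        for i in range(n):
            phase = phase_of(i, phase0)
            new_cycle = i > 0 and phase < phase_of(i - 1, phase0)
            if new_cycle:
                anchor_frame = i
                anchor = to_world(i, home + [leg_stride * duty / 2, 0])
            if phase < duty:
                kp[i, 7 + leg_idx] = anchor
            else:
                swing[i, leg_idx] = True
                u = (phase - duty) / (1.0 - duty)
                lift = to_world(anchor_frame, home + [leg_stride * duty / 2, 0])
                ego_target = home + [leg_stride * duty / 2, 0]
                # touch-down point of the NEXT cycle, estimated in world
                land_frame = min(n - 1, anchor_frame + int(round(1.0 / params.cadence / dt)))
                land = to_world(land_frame, ego_target)
                kp[i, 7 + leg_idx] = lift + _swing_profile(np.array([u]))[0] * (
                    land - lift
                )
    if params.lateral_noise > 0:
        kp += rng.normal(0.0, params.lateral_noise, size=kp.shape)

    # one neighbour fly at a constant offset from the path
    neigh = com + np.array([0.0, params.neighbor_distance * params.body_length])
    track = RawArenaTrack(
        keypoints=kp,
        neighbors=neigh[:, None, :],
        body_length=params.body_length,
    )
    speed = np.linalg.norm(np.gradient(com, dt, axis=0), axis=1)
    return SynthWalkResult(track, swing, speed, heading, params)


# ---------------------------------------------------------------------------
# flight trajectories
# ---------------------------------------------------------------------------

@dataclass
class FlightTrajectory:
    """CoM + orientation samples at a fixed control step (SI units)."""

    t: np.ndarray  # (n,) s
    position: np.ndarray  # (n, 3) m
    quaternion: np.ndarray  # (n, 4) (w, x, y, z)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan


@dataclass
class SynthFlightParams:
    """Flight-trajectory template parameters.

    Speeds go up to the ~30 cm/s cruising range; the saccade template
    performs a smooth rapid yaw turn with a single acceleration peak.
    """

    template: str = "straight"  # straight | saccade | hover
    speed: float = 0.3  # m/s
    saccade_yaw_deg: float = 90.0
    saccade_duration: float = 0.05  # s
    duration: float = 0.2  # s
    altitude: float = 0.02  # m
    seed: int = 0

    def __post_init__(self):
        if self.template not in ("straight", "saccade", "hover"):
            raise ValueError(f"unknown template {self.template!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def synth_flight_traj(params: SynthFlightParams) -> FlightTrajectory:
    """Generate a C1-smooth CoM + quaternion trajectory at 0.2 ms steps."""
    dt = FLIGHT_CONTROL_DT
    n = int(round(params.duration / dt)) + 1
    t = np.arange(n) * dt
    if params.template == "hover":
        pos = np.tile([0.0, 0.0, params.altitude], (n, 1))
        quat = np.tile([1.0, 0, 0, 0], (n, 1))
        return FlightTrajectory(t, pos, quat)
    if params.template == "straight":
        pos = np.stack(
            [params.speed * t, np.zeros(n), np.full(n, params.altitude)], axis=1
        )
        quat = np.tile([1.0, 0, 0, 0], (n, 1))
        return FlightTrajectory(t, pos, quat)
    # saccade: heading follows a smooth step centred mid-trajectory
    t0 = 0.5 * params.duration
    tau = params.saccade_duration / 6.0
    total = np.deg2rad(params.saccade_yaw_deg)
    heading = total * 0.5 * (1.0 + np.tanh((t - t0) / tau))
    vel = np.stack(
        [params.speed * np.cos(heading), params.speed * np.sin(heading),
         np.zeros(n)], axis=1
    )
    pos = np.concatenate(
        [np.zeros((1, 3)), np.cumsum(0.5 * (vel[1:] + vel[:-1]) * dt, axis=0)]
    )
    pos[:, 2] = params.altitude
    quat = np.stack(
        [quat_from_axis_angle([0, 0, 1.0], h) for h in heading]
    )
    return FlightTrajectory(t, pos, quat)


# ---------------------------------------------------------------------------
# mirror augmentation
# ---------------------------------------------------------------------------

def mirror_trajectory(traj: FlightTrajectory) -> FlightTrajectory:
    """Reflect across the vertical xz-plane (y -> -y).

    Positions map (x, y, z) -> (x, -y, z); quaternions conjugate by the
    reflection, (w, x, y, z) -> (w, -x, y, -z), which equals converting
    to a rotation matrix R and back from M R M with M = diag(1, -1, 1).
    """
    pos = traj.position * np.array([1.0, -1.0, 1.0])
    q = traj.quaternion
    quat = np.stack([q[:, 0], -q[:, 1], q[:, 2], -q[:, 3]], axis=1)
    return FlightTrajectory(traj.t.copy(), pos, quat)


def mirror_augment(trajectories: list) -> list:
    """Double a trajectory set by appending the mirrored counterparts."""
    return list(trajectories) + [mirror_trajectory(tr) for tr in trajectories]
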