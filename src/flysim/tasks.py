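"""Imitation-environment contracts and the vision-task world.

Imitation control: a high-level steering command specifies the desired
egocentric change in CoM position and orientation per control step; the
reward is a product of Gaussian kernels over CoM, orientation and
keypoint errors (1 at perfect tracking); failure terminates the episode
without value bootstrapping while hitting the time limit bootstraps.

Vision world: procedurally sampled raised-cosine bump obstacles (height
0-2 cm, length 2-4 cm, giving inclinations up to 72 degrees), a
sine-shaped trench corridor, and two low-resolution head-fixed eye
cameras (32 x 32 pixels, 150-degree field of view) rendered by ray
casting against the terrain heightfield.

Policy actions live in the canonical range [-1, 1] and map affinely to
actuator ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from flysim.rotations import quat_conj, quat_geodesic_angle, quat_mul, quat_rotate

logger = logging.getLogger(__name__)


class ContractError(ValueError):
    pass


# ---------------------------------------------------------------------------
# steering, reward, termination
# ---------------------------------------------------------------------------

@dataclass
class SteeringCommand:
    """Egocentric per-step displacement (m) and axis-angle rotation (rad)."""

    delta_position: np.ndarray
    delta_orientation: np.ndarray

    def __post_init__(self):
        self.delta_position = np.asarray(self.delta_position, dtype=float)
        self.delta_orientation = np.asarray(self.delta_orientation, dtype=float)
        if not (
            np.all(np.isfinite(self.delta_position))
            and np.all(np.isfinite(self.delta_orientation))
        ):
            raise ContractError("steering command must be finite")


def steering_from_reference(traj, t: float, control_dt: float) -> SteeringCommand:
    """Steering command taking the fly from the reference pose at ``t`` to
    the pose at ``t + control_dt``, expressed in the fly's local frame."""
    dt = traj.dt
    i = t / dt
    j = (t + control_dt) / dt
    if t < -1e-12 or j > traj.n_frames - 1 + 1e-9:
        raise ContractError("time outside the reference trajectory")
    i = int(round(i))
    j = int(round(j))
    q = traj.quaternion[i]
    dp_world = traj.position[j] - traj.position[i]
    dp_local = quat_rotate(quat_conj(q), dp_world)
    dq = quat_mul(quat_conj(q), traj.quaternion[j])
    ang = 2.0 * np.arccos(np.clip(abs(dq[0]), -1.0, 1.0))
    if ang > 0 and np.linalg.norm(dq[1:]) > 0:
        axis = np.sign(dq[0]) * dq[1:] / np.linalg.norm(dq[1:])
        rot = axis * ang
    else:
        rot = np.zeros(3)
    return SteeringCommand(dp_local, rot)


@dataclass
class RewardConfig:
    """Gaussian kernel widths for the imitation reward terms."""

    sigma_com: float = 5e-4  # m (0.05 cm)
    sigma_ori: float = np.deg2rad(10.0)  # rad
    sigma_keypoint: float = 5e-4  # m (0.05 cm)

    def __post_init__(self):
        if min(self.sigma_com, self.sigma_ori, self.sigma_keypoint) <= 0:
            raise ContractError("kernel widths must be > 0")


def imitation_reward(
    com_error: float,
    orientation_error: float,
    keypoint_error: float,
    cfg: RewardConfig | None = None,
) -> float:
    """Product of Gaussian kernels exp(-e^2 / 2 sigma^2) over the three
    tracking errors; equals 1 iff all errors are zero and decreases
    strictly in each."""
    cfg = cfg if cfg is not None else RewardConfig()
    return float(
        np.exp(-0.5 * (com_error / cfg.sigma_com) ** 2)
        * np.exp(-0.5 * (orientation_error / cfg.sigma_ori) ** 2)
        * np.exp(-0.5 * (keypoint_error / cfg.sigma_keypoint) ** 2)
    )


class EpisodeState(Enum):
    RUNNING = "running"
    TIME_LIMIT = "time_limit"
    FAILURE = "failure"


@dataclass
class EpisodeStatus:
    """Termination outcome; bootstrapping only at the time limit."""

    state: EpisodeState
    bootstrap: bool

    def __post_init__(self):
        if self.state is EpisodeState.FAILURE and self.bootstrap:
            raise ContractError("failure terminations never bootstrap")


def check_termination(
    position,
    step_count: int,
    episode_limit: int,
    terrain=None,
    tracking_error: float | None = None,
    tracking_limit: float = np.inf,
) -> EpisodeStatus:
    """Failure on terrain contact or tracking blow-up; otherwise time limit
    (bootstrap) or running."""
    position = np.asarray(position, dtype=float)
    if terrain is not None and terrain.collides(position):
        return EpisodeStatus(EpisodeState.FAILURE, False)
    if tracking_error is not None and tracking_error > tracking_limit:
        return EpisodeStatus(EpisodeState.FAILURE, False)
    if step_count >= episode_limit:
        return EpisodeStatus(EpisodeState.TIME_LIMIT, True)
    return EpisodeStatus(EpisodeState.RUNNING, False)


# ---------------------------------------------------------------------------
# terrains (bench units: cm)
# ---------------------------------------------------------------------------

@dataclass
class BumpTerrain:
    """Raised-cosine bump: z(x) = (h/2)(1 - cos(2 pi x / L)) on [0, L]."""

    height: float  # cm, in [0, 2]
    length: float  # cm, in [2, 4]
    x_start: float = 0.0  # cm

    def __post_init__(self):
        if not 0.0 <= self.height <= 2.0:
            raise ContractError("bump height outside the [0, 2] cm range")
        if not 2.0 <= self.length <= 4.0:
            raise ContractError("bump length outside the [2, 4] cm range")

    def height_at(self, x) -> np.ndarray:
        u = np.asarray(x, dtype=float) - self.x_start
        z = 0.5 * self.height * (1.0 - np.cos(2 * np.pi * u / self.length))
        return np.where((u >= 0) & (u <= self.length), z, 0.0)

    def max_inclination_deg(self) -> float:
        """atan of the steepest slope: atan(pi h / L), degrees."""
        return float(np.rad2deg(np.arctan(np.pi * self.height / self.length)))

    def collides(self, position) -> bool:
        x, _, z = np.asarray(position, dtype=float)
        return bool(z <= self.height_at(x))

    def heightfield(self, x_grid, y_grid) -> np.ndarray:
        hx = self.height_at(np.asarray(x_grid))
        return np.tile(hx[None, :], (len(y_grid), 1))


def sample_bump(rng: np.random.Generator, x_start: float = 0.0) -> BumpTerrain:
    """Bump with height ~ U[0, 2] cm and length ~ U[2, 4] cm."""
    return BumpTerrain(
        height=float(rng.uniform(0.0, 2.0)),
        length=float(rng.uniform(2.0, 4.0)),
        x_start=x_start,
    )


def bump_height(terrain: BumpTerrain, x) -> np.ndarray:
    return terrain.height_at(x)


def max_inclination(terrain: BumpTerrain) -> float:
    return terrain.max_inclination_deg()


@dataclass
class TrenchTerrain:
    """Sine-shaped trench sunk into level ground (z = 0).

    The corridor centreline is ``y = amplitude sin(2 pi x / period)``;
    inside the corridor the floor is at ``-depth``, outside the ground is
    solid at z = 0.
    """

    amplitude: float = 1.0  # cm
    period: float = 10.0  # cm
    width: float = 1.0  # cm
    depth: float = 1.0  # cm

    def centerline(self, x) -> np.ndarray:
        return self.amplitude * np.sin(2 * np.pi * np.asarray(x, dtype=float)
                                       / self.period)

    def inside(self, position) -> bool:
        x, y, z = np.asarray(position, dtype=float)
        lateral = abs(y - float(self.centerline(x)))
        return bool(lateral < self.width / 2 and -self.depth < z)

    def collides(self, position) -> bool:
        x, y, z = np.asarray(position, dtype=float)
        if z > 0:
            return False
        if z <= -self.depth:
            return True
        return abs(y - float(self.centerline(x))) >= self.width / 2

    def heightfield(self, x_grid, y_grid) -> np.ndarray:
        x = np.asarray(x_grid)[None, :]
        y = np.asarray(y_grid)[:, None]
        inside = np.abs(y - self.centerline(x)) < self.width / 2
        return np.where(inside, -self.depth, 0.0)


def trench_path(amplitude=1.0, period=10.0, width=1.0, depth=1.0) -> TrenchTerrain:
    return TrenchTerrain(amplitude, period, width, depth)


def collision_check(position, terrain) -> bool:
    return terrain.collides(position)


def export_heightfield(terrain, x_grid, y_grid, path) -> None:
    """Write the terrain height (cm) on a grid as CSV (rows = y)."""
    import pandas as pd

    z = terrain.heightfield(x_grid, y_grid)
    df = pd.DataFrame(z, index=np.asarray(y_grid), columns=np.asarray(x_grid))
    df.index.name = "y_cm"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# eye cameras
# ---------------------------------------------------------------------------

@dataclass
class EyeCamera:
    """Head-fixed pinhole camera: 32 x 32 pixels over a 150-degree FOV."""

    yaw_deg: float  # camera axis yaw relative to the head, +left
    resolution: int = 32
    fov_deg: float = 150.0
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)


def default_eye_cameras() -> tuple[EyeCamera, EyeCamera]:
    return (EyeCamera(yaw_deg=30.0), EyeCamera(yaw_deg=-30.0))


def _ray_directions(cam: EyeCamera) -> np.ndarray:
    """(res, res, 3) unit rays in the camera frame (+x optical axis)."""
    half = np.tan(np.deg2rad(cam.fov_deg) / 2.0)
    r = cam.resolution
    # pixel centres
    u = (np.arange(r) + 0.5) / r * 2.0 - 1.0
    yy, zz = np.meshgrid(u * half, -u * half, indexing="xy")
    d = np.stack([np.ones_like(yy), yy, zz], axis=2)
    return d / np.linalg.norm(d, axis=2, keepdims=True)


def eye_render(
    head_position,
    head_yaw: float,
    terrain,
    cameras: tuple[EyeCamera, EyeCamera] | None = None,
    max_range: float = 20.0,
    n_march: int = 200,
) -> np.ndarray:
    """Ray-cast the terrain into two 32 x 32 grayscale frames.

    Positions in cm; ``head_yaw`` in radians about +z.  Each pixel holds
    a depth shade ``1 / (1 + distance)`` of the first terrain hit along
    its ray, or 0 (sky) when nothing is hit within ``max_range`` cm.
    Deterministic given pose and terrain.  Output shape (2, 32, 32).
    """
    if cameras is None:
        cameras = default_eye_cameras()
    head_position = np.asarray(head_position, dtype=float)
    frames = []
    ts = np.linspace(0.0, max_range, n_march)[1:]
    for cam in cameras:
        yaw = head_yaw + np.deg2rad(cam.yaw_deg)
        c, s = np.cos(yaw), np.sin(yaw)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        dirs = _ray_directions(cam) @ rot.T
        origin = head_position + rot @ cam.offset
        res = cam.resolution
        img = np.zeros((res, res))
        pts = origin[None, None, None, :] + dirs[:, :, None, :] * ts[None, None, :, None]
        # evaluate terrain height under every sample point
        x = pts[..., 0].ravel()
        y = pts[..., 1].ravel()
        z = pts[..., 2].ravel()
        h = _terrain_height(terrain, x, y)
        below = (z <= h).reshape(res, res, ts.size)
        hit = below.argmax(axis=2)
        has_hit = below.any(axis=2)
        img = np.where(has_hit, 1.0 / (1.0 + ts[hit]), 0.0)
        frames.append(img)
    return np.stack(frames)


def _terrain_height(terrain, x, y) -> np.ndarray:
    if isinstance(terrain, BumpTerrain):
        return terrain.height_at(x)
    if isinstance(terrain, TrenchTerrain):
        inside = np.abs(y - terrain.centerline(x)) < terrain.width / 2
        return np.where(inside, -terrain.depth, 0.0)
    raise ContractError(f"unknown terrain {type(terrain).__name__}")


# ---------------------------------------------------------------------------
# action canonicalization
# ---------------------------------------------------------------------------

def action_rescale(a, ranges) -> np.ndarray:
    """Map canonical actions in [-1, 1]^n affinely onto actuator ranges.

    ``ranges`` is (n, 2) with lo < hi.  Out-of-range actions are clamped
    with a warning; a = 0 maps to the range midpoint, a = +-1 to the
    endpoints.
    """
    a = np.asarray(a, dtype=float)
    ranges = np.asarray(ranges, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(ranges)) or np.any(ranges[:, 0] >= ranges[:, 1]):
        raise ContractError("actuator ranges must be finite with lo < hi")
    if np.any(np.abs(a) > 1.0):
        logger.warning("canonical action outside [-1, 1]; clamped")
        a = np.clip(a, -1.0, 1.0)
    mid = ranges.mean(axis=1)
    half = 0.5 * (ranges[:, 1] - ranges[:, 0])
    return mid + a * half


def action_canonicalize(u, ranges) -> np.ndarray:
    """Inverse of :func:`action_rescale`."""
    u = np.asarray(u, dtype=float)
    ranges = np.asarray(ranges, dtype=float).reshape(-1, 2)
    mid = ranges.mean(axis=1)
    half = 0.5 * (ranges[:, 1] - ranges[:, 0])
    return (u - mid) / half
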