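"""Walking reference-data preparation.

Top-down arena videos give 13 tracked keypoints per frame at 150 fps
(3 head, 3 thorax, abdomen tip and the 6 leg tips).  This module turns
such 2D tracks into 3D reference snippets for imitation:

1. :func:`select_snippets` — keep contiguous stretches of clean forward
   walking: far enough from other flies, moving mostly parallel to the
   body axis, at least 20 frames (133 ms, roughly one step cycle) long,
   and with a leg-tip/CoM mean-speed ratio below 1.5;
2. :func:`resample` — linear interpolation from the 6.7 ms camera step
   to the 2 ms control step;
3. :func:`label_swing_stance` — hysteresis thresholding of egocentric
   leg-tip speeds;
4. :func:`lift_to_3d` — complement x, y with z: stance leg tips stay on
   the ground (z = 0), each swing traces ``z = A sin(x)`` with x running
   0..pi over the swing and per-leg-pair amplitudes A (T1 0.086, T2
   0.047, T3 0.051 cm); body keypoints sit at a fixed height and pitch.

Track coordinates are in cm (bench units) throughout this module, since
that is how arena data arrives; conversions to SI happen downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

FRAME_RATE_HZ = 150.0
FRAME_DT_MS = 1000.0 / FRAME_RATE_HZ
MIN_SNIPPET_FRAMES = 20
MAX_TIP_COM_SPEED_RATIO = 1.5

#: keypoint order within a track
KEYPOINT_NAMES = (
    "head_top", "head_left", "head_right",
    "thorax_front", "thorax_left", "thorax_right",
    "abdomen_tip",
    "tip_T1_L", "tip_T1_R", "tip_T2_L", "tip_T2_R", "tip_T3_L", "tip_T3_R",
)
LEG_TIP_SLICE = slice(7, 13)
LEG_ORDER = ("T1_L", "T1_R", "T2_L", "T2_R", "T3_L", "T3_R")

#: leg-tip swing-arc amplitudes, cm, per leg pair
LEG_ARC_AMPLITUDES_CM = {"T1": 0.086, "T2": 0.047, "T3": 0.051}

#: hysteresis thresholds on egocentric leg-tip speed, cm/s
SWING_SPEED_HI = 0.3
SWING_SPEED_LO = 0.15
MIN_PHASE_FRAMES = 2


class ContractError(ValueError):
    pass


@dataclass
class RawArenaTrack:
    """Per-frame 13 keypoints (cm) at 150 fps plus neighbour-fly positions."""

    keypoints: np.ndarray  # (n, 13, 2) cm
    neighbors: np.ndarray  # (n, k, 2) cm; k may be 0
    body_length: float  # cm
    frame_rate: float = FRAME_RATE_HZ

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.neighbors = np.asarray(self.neighbors, dtype=float)
        if self.keypoints.ndim != 3 or self.keypoints.shape[1:] != (13, 2):
            raise ContractError("keypoints must have shape (n, 13, 2)")
        if self.neighbors.size and self.neighbors.shape[0] != self.keypoints.shape[0]:
            raise ContractError("neighbors must align with keypoints frames")

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]

    @property
    def dt(self) -> float:
        """Frame period, seconds."""
        return 1.0 / self.frame_rate

    def com(self) -> np.ndarray:
        """CoM proxy: centroid of the three thorax keypoints, (n, 2) cm."""
        return self.keypoints[:, 3:6].mean(axis=1)

    def body_axis(self) -> np.ndarray:
        """Unit body axis per frame: thorax front minus rear midpoint."""
        front = self.keypoints[:, 3]
        rear = 0.5 * (self.keypoints[:, 4] + self.keypoints[:, 5])
        ax = front - rear
        norm = np.linalg.norm(ax, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return ax / norm


@dataclass
class Snippet:
    """A contiguous frame range of a track passing all selection criteria."""

    track: RawArenaTrack
    start: int
    stop: int  # exclusive

    def __post_init__(self):
        if self.stop - self.start < MIN_SNIPPET_FRAMES:
            raise ContractError(
                f"snippet must span >= {MIN_SNIPPET_FRAMES} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def duration_ms(self) -> float:
        """Duration counted as n_frames camera periods (20 -> 133.3 ms)."""
        return self.n_frames * 1000.0 / self.track.frame_rate

    @property
    def keypoints(self) -> np.ndarray:
        return self.track.keypoints[self.start : self.stop]


@dataclass
class Lifted3DSnippet:
    """13 keypoints x 3D at the control step, with swing labels."""

    keypoints3d: np.ndarray  # (n, 13, 3) cm
    swing: np.ndarray  # (n, 6) bool, True during swing
    dt: float  # s
    body_height: float = 0.0  # cm
    body_pitch: float = 0.0  # rad
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("keypoints3d", data=self.keypoints3d)
            fh.create_dataset("labels", data=self.swing.astype(np.uint8))
            g = fh.create_group("meta")
            g.attrs["dt"] = self.dt
            g.attrs["body_height"] = self.body_height
            g.attrs["body_pitch"] = self.body_pitch
            for k, v in self.meta.items():
                g.attrs[k] = v

    @classmethod
    def load(cls, path) -> "Lifted3DSnippet":
        with h5py.File(path, "r") as fh:
            g = fh["meta"]
            meta = {
                k: g.attrs[k]
                for k in g.attrs
                if k not in ("dt", "body_height", "body_pitch")
            }
            return cls(
                keypoints3d=fh["keypoints3d"][()],
                swing=fh["labels"][()].astype(bool),
                dt=float(g.attrs["dt"]),
                body_height=float(g.attrs["body_height"]),
                body_pitch=float(g.attrs["body_pitch"]),
                meta=meta,
            )


# ---------------------------------------------------------------------------
# snippet selection
# ---------------------------------------------------------------------------

def _velocities(points: np.ndarray, dt: float) -> np.ndarray:
    """Central differences interior, one-sided at the ends."""
    return np.gradient(points, dt, axis=0)


def frame_criteria(track: RawArenaTrack) -> np.ndarray:
    """Boolean per-frame mask of criteria (i) and (ii).

    (i) distance to every other fly exceeds one body length;
    (ii) the CoM velocity component parallel to the body axis exceeds the
    perpendicular component (in magnitude).
    """
    n = track.n_frames
    ok = np.ones(n, dtype=bool)
    if track.neighbors.size:
        com = track.com()[:, None, :]
        dist = np.linalg.norm(track.neighbors - com, axis=2)
        ok &= dist.min(axis=1) > track.body_length
    v = _velocities(track.com(), track.dt)
    ax = track.body_axis()
    v_par = np.abs(np.einsum("ij,ij->i", v, ax))
    v_perp = np.abs(v[:, 0] * ax[:, 1] - v[:, 1] * ax[:, 0])
    ok &= v_par > v_perp
    return ok


def _tip_com_speed_ratio(track: RawArenaTrack, start: int, stop: int) -> float:
    dt = track.dt
    com_speed = np.linalg.norm(
        _velocities(track.com()[start:stop], dt), axis=1
    ).mean()
    tips = track.keypoints[start:stop, LEG_TIP_SLICE]
    tip_speed = np.linalg.norm(
        np.gradient(tips, dt, axis=0), axis=2
    ).mean()
    if com_speed == 0:
        return np.inf
    return float(tip_speed / com_speed)


def select_snippets(track: RawArenaTrack) -> list[Snippet]:
    """Maximal runs satisfying (i)+(ii), filtered by length and (iv)."""
    ok = frame_criteria(track)
    snippets = []
    n = track.n_frames
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        if j - i >= MIN_SNIPPET_FRAMES:
            if _tip_com_speed_ratio(track, i, j) < MAX_TIP_COM_SPEED_RATIO:
                snippets.append(Snippet(track, i, j))
        i = j
    return snippets


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(points: np.ndarray, dt_in: float, dt_out: float = 2e-3) -> np.ndarray:
    """Linear interpolation of a (n, ...) time series to a finer step.

    The snippet duration is counted as ``n * dt_in`` (one camera period
    per frame), so a 20-frame snippet at 150 fps spans 133.3 ms and
    resamples to 67 frames at 2 ms; beyond the last sample the value is
    held.  Endpoints are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ContractError("need at least 2 frames to resample")
    n = pts.shape[0]
    t_in = np.arange(n) * dt_in
    duration = n * dt_in
    n_out = int(np.floor(duration / dt_out)) + 1
    t_out = np.arange(n_out) * dt_out
    flat = pts.reshape(n, -1)
    out = np.empty((n_out, flat.shape[1]))
    for k in range(flat.shape[1]):
        out[:, k] = np.interp(t_out, t_in, flat[:, k])
    return out.reshape((n_out,) + pts.shape[1:])


# ---------------------------------------------------------------------------
# swing/stance labelling
# ---------------------------------------------------------------------------

def egocentric_tips(keypoints: np.ndarray) -> np.ndarray:
    """Leg tips in the fly frame (origin CoM proxy, x along body axis)."""
    com = keypoints[:, 3:6].mean(axis=1)
    front = keypoints[:, 3]
    rear = 0.5 * (keypoints[:, 4] + keypoints[:, 5])
    ax = front - rear
    ax /= np.maximum(np.linalg.norm(ax, axis=1, keepdims=True), 1e-12)
    perp = np.stack([-ax[:, 1], ax[:, 0]], axis=1)
    rel = keypoints[:, LEG_TIP_SLICE] - com[:, None, :]
    x = np.einsum("nkj,nj->nk", rel, ax)
    y = np.einsum("nkj,nj->nk", rel, perp)
    return np.stack([x, y], axis=2)


def _hysteresis(speed: np.ndarray, hi: float, lo: float) -> np.ndarray:
    out = np.zeros(speed.shape, dtype=bool)
    state = False
    for i, s in enumerate(speed):
        if state and s < lo:
            state = False
        elif not state and s > hi:
            state = True
        out[i] = state
    return out


def _enforce_min_duration(labels: np.ndarray, min_frames: int) -> np.ndarray:
    out = labels.copy()
    n = out.size
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j - i < min_frames and i > 0:
            out[i:j] = out[i - 1]
        i = j
    return out


def label_swing_stance(
    keypoints: np.ndarray,
    dt: float,
    v_hi: float = SWING_SPEED_HI,
    v_lo: float = SWING_SPEED_LO,
) -> np.ndarray:
    """(n, 6) bool swing labels from egocentric leg-tip velocities.

    In the fly's frame a stance tip drifts backwards at the walking
    speed while a swing tip shoots forwards, so the discriminating
    signal is the signed forward (body-axis) component of the tip
    velocity: a leg enters swing when it rises above ``v_hi`` (cm/s)
    and returns to stance below ``v_lo``; phases shorter than two
    frames are merged into their predecessor.
    """
    tips = egocentric_tips(keypoints)
    labels = np.zeros(tips.shape[:2], dtype=bool)
    for leg in range(6):
        # forward difference: frame i is labelled by the motion during
        # [t_i, t_i + dt), matching the frame-start phase convention
        x = tips[:, leg, 0]
        v_fwd = np.empty_like(x)
        v_fwd[:-1] = np.diff(x) / dt
        v_fwd[-1] = v_fwd[-2] if x.size > 1 else 0.0
        lab = _hysteresis(v_fwd, v_hi, v_lo)
        labels[:, leg] = _enforce_min_duration(lab, MIN_PHASE_FRAMES)
    return labels


def duty_factor(swing: np.ndarray) -> float:
    """Stance fraction of frames, pooled over legs."""
    return float(1.0 - swing.mean())


# ---------------------------------------------------------------------------
# 2D -> 3D lifting
# ---------------------------------------------------------------------------

def default_body_height_cm() -> float:
    """Standing body height from the model's rest stance (FK of q = 0)."""
    from flysim import units
    from flysim.body import build_default_fly, forward_kinematics

    tree = build_default_fly()
    frames, _ = forward_kinematics(tree, tree.zero_pose())
    tip_z = np.mean(
        [frames[f"{leg}_claw"][0][2] for leg in
         ("T1_L", "T1_R", "T2_L", "T2_R", "T3_L", "T3_R")]
    )
    return float(units.m_to_cm(-tip_z))


def lift_to_3d(
    keypoints: np.ndarray,
    swing: np.ndarray,
    dt: float,
    amplitudes: dict | None = None,
    body_height: float | None = None,
    body_pitch: float = 0.0,
) -> Lifted3DSnippet:
    """Add the vertical dimension to a 2D snippet.

    Stance leg tips keep z = 0.  Each contiguous swing maps its progress
    to x in [0, pi] and traces ``z = A sin(x)`` with the per-leg-pair
    amplitude A (so mid-swing reaches exactly A).  Body keypoints are
    placed at the fixed standing height, tilted by the fixed pitch about
    the pitch axis through the CoM.
    """
    if amplitudes is None:
        amplitudes = LEG_ARC_AMPLITUDES_CM
    if body_height is None:
        body_height = default_body_height_cm()
    n = keypoints.shape[0]
    if swing.shape != (n, 6):
        raise ContractError("labels inconsistent with snippet length")
    z = np.zeros((n, 13))
    z[:, :7] = body_height
    if body_pitch != 0.0:
        com = keypoints[:, 3:6].mean(axis=1)
        ax = keypoints[:, 3] - 0.5 * (keypoints[:, 4] + keypoints[:, 5])
        ax /= np.maximum(np.linalg.norm(ax, axis=1, keepdims=True), 1e-12)
        for k in range(7):
            fwd = np.einsum("nj,nj->n", keypoints[:, k] - com, ax)
            z[:, k] = body_height + fwd * np.tan(body_pitch)
    for leg in range(6):
        pair = LEG_ORDER[leg][:2]
        amp = amplitudes[pair]
        lab = swing[:, leg]
        i = 0
        while i < n:
            if not lab[i]:
                i += 1
                continue
            j = i
            while j < n and lab[j]:
                j += 1
            length = j - i
            # swing progress x: 0 at lift-off, pi at touch-down
            x = np.pi * (np.arange(length) + 0.5) / length
            z[i:j, 7 + leg] = amp * np.sin(x)
            i = j
    kp3 = np.concatenate([keypoints, z[:, :, None]], axis=2)
    return Lifted3DSnippet(
        keypoints3d=kp3,
        swing=swing.copy(),
        dt=dt,
        body_height=body_height,
        body_pitch=body_pitch,
    )


def finite_diff_velocities(q_traj: np.ndarray, dt: float) -> np.ndarray:
    """dq/dt: central differences interior, one-sided at the endpoints."""
    q = np.asarray(q_traj, dtype=float)
    if q.shape[0] < 2:
        raise ContractError("need at least 2 frames")
    return np.gradient(q, dt, axis=0)
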