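"""Gait and flight evaluation statistics.

Walking: stance counts versus speed, circular statistics of swing-onset
phases relative to the front-left leg, and left/right swing-length
asymmetry during turning.  Flight: CoM/orientation tracking errors,
saccade-aligned kinematic profiles, and steady/unsteady wing-beat
classification by body acceleration.

Circular quantities are handled on the unit circle; the circular median
of a phase sample is the observed angle minimizing the mean absolute arc
distance (ties broken by the smallest angle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flysim.rotations import quat_conj, quat_geodesic_angle, quat_mul, quat_rotate

LEG_ORDER = ("T1_L", "T1_R", "T2_L", "T2_R", "T3_L", "T3_R")


class ContractError(ValueError):
    pass


@dataclass
class GaitRecord:
    """Per-frame stance labels (six legs, L1 R1 L2 R2 L3 R3) and CoM speed."""

    stance: np.ndarray  # (n, 6) bool, True when the leg is on the ground
    speed: np.ndarray  # (n,) cm/s
    dt: float  # s

    def __post_init__(self):
        self.stance = np.asarray(self.stance, dtype=bool)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.stance.ndim != 2 or self.stance.shape[1] != 6:
            raise ContractError("stance must have shape (n, 6)")
        if self.speed.shape[0] != self.stance.shape[0]:
            raise ContractError("speed must align with stance frames")

    @property
    def mean_speed(self) -> float:
        return float(self.speed.mean())


# ---------------------------------------------------------------------------
# tracking errors
# ---------------------------------------------------------------------------

def tracking_errors(model_pos, model_quat, ref_pos, ref_quat) -> dict:
    """Per-frame CoM distance and orientation geodesic angle + percentiles.

    Position error is the Euclidean distance (input units); orientation
    error is ``2 acos(|<q1, q2>|)`` in degrees.  Symmetric in its
    arguments.
    """
    model_pos = np.asarray(model_pos, dtype=float)
    ref_pos = np.asarray(ref_pos, dtype=float)
    model_quat = np.asarray(model_quat, dtype=float)
    ref_quat = np.asarray(ref_quat, dtype=float)
    if model_pos.shape != ref_pos.shape or model_quat.shape != ref_quat.shape:
        raise ContractError("model and reference trajectories must align")
    pos_err = np.linalg.norm(model_pos - ref_pos, axis=1)
    ori_err = np.array(
        [
            np.rad2deg(quat_geodesic_angle(q1, q2))
            for q1, q2 in zip(model_quat, ref_quat)
        ]
    )
    summary = {}
    for name, err in (("position", pos_err), ("orientation_deg", ori_err)):
        summary[name] = {
            "per_frame": err,
            "median": float(np.median(err)),
            "p25": float(np.percentile(err, 25)),
            "p75": float(np.percentile(err, 75)),
        }
    return summary


# ---------------------------------------------------------------------------
# stance statistics
# ---------------------------------------------------------------------------

def mean_legs_in_stance(
    records: list[GaitRecord],
    speed_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean simultaneous stance count per snippet, binned by mean speed.

    Default bins are 0.25 cm/s wide over [0, 4] cm/s.  Returns one row
    per non-empty bin with the across-snippet mean.
    """
    if speed_bins is None:
        speed_bins = np.arange(0.0, 4.25, 0.25)
    rows = []
    for rec in records:
        rows.append(
            {
                "mean_speed": rec.mean_speed,
                "mean_stance_count": float(rec.stance.sum(axis=1).mean()),
            }
        )
    df = pd.DataFrame(rows)
    df["speed_bin"] = pd.cut(df["mean_speed"], speed_bins, include_lowest=True)
    out = (
        df.groupby("speed_bin", observed=True)["mean_stance_count"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_legs_in_stance", "count": "n_snippets"})
    )
    out["bin_center"] = [iv.mid for iv in out["speed_bin"]]
    return out


# ---------------------------------------------------------------------------
# circular phase statistics
# ---------------------------------------------------------------------------

def circular_median(angles) -> float:
    """Angle among the sample minimizing mean absolute arc distance.

    Ties are broken by the smallest angle in [0, 2 pi).
    """
    a = np.mod(np.asarray(angles, dtype=float), 2 * np.pi)
    if a.size == 0:
        raise ContractError("empty phase sample")
    diff = np.abs(a[:, None] - a[None, :])
    arc = np.minimum(diff, 2 * np.pi - diff)
    cost = arc.mean(axis=1)
    best = cost.min()
    return float(np.min(a[cost <= best + 1e-15]))


def swing_onsets(swing_col: np.ndarray) -> np.ndarray:
    """Frame indices where a leg lifts off (stance -> swing)."""
    s = np.asarray(swing_col, dtype=bool)
    return np.where(s[1:] & ~s[:-1])[0] + 1


def swing_onset_phases(
    swing: np.ndarray, reference_leg: int = 0
) -> dict[int, np.ndarray]:
    """Swing-onset phase of each leg within the reference leg's cycle.

    ``swing`` is (n, 6) with True during swing; the reference leg's
    consecutive swing onsets delimit cycles, and every other onset inside
    a cycle maps to an angle in [0, 2 pi).  Returns per-leg phase arrays;
    use :func:`circular_median` to summarize.
    """
    swing = np.asarray(swing, dtype=bool)
    ref = swing_onsets(swing[:, reference_leg])
    if ref.size < 2:
        raise ContractError("reference leg must complete at least one cycle")
    phases: dict[int, list] = {leg: [] for leg in range(6)}
    for leg in range(6):
        onsets = swing_onsets(swing[:, leg])
        for o in onsets:
            k = np.searchsorted(ref, o, side="right") - 1
            if k < 0 or k >= ref.size - 1:
                continue
            span = ref[k + 1] - ref[k]
            phases[leg].append(2 * np.pi * (o - ref[k]) / span)
    return {leg: np.array(v) for leg, v in phases.items()}


# ---------------------------------------------------------------------------
# turning asymmetry
# ---------------------------------------------------------------------------

def swing_lengths(ego_tips: np.ndarray, swing: np.ndarray) -> dict[int, np.ndarray]:
    """Per-leg egocentric displacement of each complete swing (cm)."""
    n = ego_tips.shape[0]
    out: dict[int, list] = {leg: [] for leg in range(6)}
    for leg in range(6):
        lab = swing[:, leg]
        i = 0
        while i < n:
            if not lab[i]:
                i += 1
                continue
            j = i
            while j < n and lab[j]:
                j += 1
            if i > 0 and j < n:  # complete swing only
                out[leg].append(
                    float(np.linalg.norm(ego_tips[j - 1, leg] - ego_tips[i, leg]))
                )
            i = j
    return {leg: np.array(v) for leg, v in out.items()}


def turn_asymmetry(ego_tips: np.ndarray, swing: np.ndarray) -> float:
    """Mean left-minus-right egocentric swing length, cm.

    Near zero for straight walking; negative when turning left (the
    inside legs shorten their strides), positive when turning right.
    """
    lengths = swing_lengths(ego_tips, swing)
    left = np.concatenate([lengths[leg] for leg in (0, 2, 4)])
    right = np.concatenate([lengths[leg] for leg in (1, 3, 5)])
    if left.size == 0 or right.size == 0:
        raise ContractError("no complete swings on one side")
    return float(left.mean() - right.mean())


# ---------------------------------------------------------------------------
# flight statistics
# ---------------------------------------------------------------------------

def _kinematics(traj):
    """Velocity, acceleration, body angular velocity, heading from a
    CoM+quaternion trajectory."""
    dt = traj.dt
    v = np.gradient(traj.position, dt, axis=0)
    a = np.gradient(v, dt, axis=0)
    n = traj.n_frames
    omega = np.zeros((n, 3))
    q = traj.quaternion
    for i in range(n - 1):
        dq = quat_mul(quat_conj(q[i]), q[i + 1])
        ang = 2.0 * np.arccos(np.clip(abs(dq[0]), -1.0, 1.0))
        if ang > 0 and np.linalg.norm(dq[1:]) > 0:
            axis = dq[1:] / np.linalg.norm(dq[1:])
            omega[i] = np.sign(dq[0]) * axis * ang / dt
    omega[-1] = omega[-2] if n > 1 else 0.0
    heading = np.array(
        [np.arctan2(*quat_rotate(qq, [1.0, 0, 0])[[1, 0]]) for qq in q]
    )
    return v, a, omega, np.unwrap(heading)


def saccade_profile(trajectories: list, window: int = 50) -> dict:
    """Align trajectories at peak |linear acceleration| and summarize.

    Returns median and quartile traces of speed, heading (relative to the
    peak instant) and body angular velocity over +-``window`` control
    steps around the peak.  Trajectories whose acceleration is flat
    (no unique peak) are excluded with a warning.
    """
    import logging

    aligned = {"speed": [], "heading": [], "omega_x": [], "omega_y": [],
               "omega_z": []}
    dt = None
    for traj in trajectories:
        v, a, omega, heading = _kinematics(traj)
        mag = np.linalg.norm(a, axis=1)
        if mag.max() - mag.min() < 1e-12:
            logging.getLogger(__name__).warning(
                "flat-acceleration trajectory excluded from saccade profile"
            )
            continue
        peak = int(np.argmax(mag))
        lo, hi = peak - window, peak + window + 1
        if lo < 0 or hi > traj.n_frames:
            continue
        dt = traj.dt
        aligned["speed"].append(np.linalg.norm(v[lo:hi], axis=1))
        aligned["heading"].append(heading[lo:hi] - heading[peak])
        aligned["omega_x"].append(omega[lo:hi, 0])
        aligned["omega_y"].append(omega[lo:hi, 1])
        aligned["omega_z"].append(omega[lo:hi, 2])
    if not aligned["speed"]:
        raise ContractError("no trajectory with a unique acceleration peak")
    t = (np.arange(2 * window + 1) - window) * dt
    out = {"t": t}
    for key, traces in aligned.items():
        arr = np.stack(traces)
        out[key] = {
            "median": np.median(arr, axis=0),
            "p25": np.percentile(arr, 25, axis=0),
            "p75": np.percentile(arr, 75, axis=0),
        }
    return out


def classify_wingbeats(
    times: np.ndarray,
    stroke_angle: np.ndarray,
    body_accel_mag: np.ndarray,
    threshold: float | None = None,
    n_phase: int = 64,
) -> dict:
    """Split wing beats into steady/unsteady by per-beat body acceleration.

    Beats are delimited by stroke reversals (maxima of the stroke angle);
    each beat's mean |body acceleration| is compared with ``threshold``
    (default: the dataset median, so 'unsteady' means above-typical
    acceleration).  Returns the per-set beat indices and median
    stroke-angle-versus-phase cycles.
    """
    times = np.asarray(times, dtype=float)
    stroke = np.asarray(stroke_angle, dtype=float)
    acc = np.asarray(body_accel_mag, dtype=float)
    # stroke reversals: local maxima
    rev = np.where((stroke[1:-1] >= stroke[:-2]) & (stroke[1:-1] > stroke[2:]))[0] + 1
    if rev.size < 2:
        raise ContractError("need at least one full wing beat")
    beat_mean_acc = np.array(
        [acc[rev[k] : rev[k + 1]].mean() for k in range(rev.size - 1)]
    )
    if threshold is None:
        threshold = float(np.median(beat_mean_acc))
    unsteady = beat_mean_acc > threshold
    grid = np.linspace(0.0, 1.0, n_phase, endpoint=False)
    cycles = {True: [], False: []}
    for k in range(rev.size - 1):
        seg = stroke[rev[k] : rev[k + 1] + 1]
        phase = np.linspace(0, 1, seg.size)
        cycles[bool(unsteady[k])].append(np.interp(grid, phase, seg))
    out = {
        "threshold": threshold,
        "steady_beats": np.where(~unsteady)[0],
        "unsteady_beats": np.where(unsteady)[0],
        "phase": grid,
    }
    for label, key in ((False, "steady_median_cycle"),
                       (True, "unsteady_median_cycle")):
        out[key] = (
            np.median(np.stack(cycles[label]), axis=0)
            if cycles[label]
            else None
        )
    return out
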