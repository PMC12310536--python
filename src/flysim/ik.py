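"""Regularized gradient-descent inverse kinematics.

Fits the articulated body model to 3D keypoint targets by minimizing

    sum_i || s_i(q) - s_i* ||^2  +  lambda || q - q0 ||^2

over the joint angles (and optionally the root pose), where ``s_i(q)``
are the world positions of registered keypoint sites and ``s_i*`` the
targets.  The regularizer pulls under-determined DoFs (a fly's 13
tracked keypoints leave many leg DoFs free) towards a reference pose
``q0`` — the default standing pose, a vector of zeros.  The default
regularization strength is 1e-4 cm^2 rad^-2 (1e-8 in SI).

Minimization is damped first-order descent on the analytic site
Jacobians: each iterate solves a Levenberg-style system
``(J^T J + lam I + mu D) step = -g`` whose damping ``mu`` is raised until
the objective decreases (the large-``mu`` limit is plain gradient
descent), and joint limits are enforced by projection after every
accepted step.  The objective is non-increasing across accepted
iterations.  Trajectories are fitted frame by frame, warm-starting each
frame from the previous fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from flysim.body import KinematicTree, Pose, ContractError, rescale
from flysim.rotations import (
    quat_from_axis_angle,
    quat_mul,
    quat_normalize,
    quat_rotate,
)

#: default regularization strength: 1e-4 cm^2 rad^-2 expressed in m^2
DEFAULT_LAMBDA_SI = 1e-8


def _skew(v):
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


@dataclass
class IKConfig:
    lam: float = DEFAULT_LAMBDA_SI  # m^2 rad^-2
    q0: np.ndarray | None = None  # reference pose; zeros by default
    step_size: float = 1.0  # initial step in the preconditioned metric
    max_iter: int = 500
    tol: float = 1e-8  # relative objective decrease
    abs_tol: float = 1e-24  # m^2: residuals at the ~1e-12 m level
    max_halvings: int = 20
    fit_root: bool = True

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step size must be > 0")

    @classmethod
    def with_lambda_cm(cls, lam_cm2: float, **kw) -> "IKConfig":
        """Config with lambda given in cm^2 rad^-2 (bench units)."""
        return cls(lam=lam_cm2 * 1e-4, **kw)


@dataclass
class IKResult:
    pose: Pose
    residuals: np.ndarray  # per-keypoint distances, m
    objective: float
    iterations: int
    converged: bool
    leg_scale: float | None = None  # set by fit_leg when rescaling


def _site_positions_and_jacobian(tree: KinematicTree, pose: Pose,
                                 site_names, free_joints):
    """World site positions plus d(site)/d(q_j) for the free joints.

    The Jacobian column of hinge j (axis a at world point o) for a site
    at p downstream of j is ``a x (p - o)``; upstream sites get zeros.
    """
    # FK with per-joint world axis and origin recorded
    frames = {}
    joint_axis_world = np.zeros((tree.n_joints, 3))
    joint_origin_world = np.zeros((tree.n_joints, 3))
    ancestors: dict[str, list[int]] = {}
    for s in tree.segments:
        if s.parent is None:
            pos = pose.root_position.copy()
            quat = quat_normalize(pose.root_orientation)
            anc: list[int] = []
        else:
            p_pos, p_quat = frames[s.parent]
            pos = p_pos + quat_rotate(p_quat, s.rest_pos)
            quat = quat_mul(p_quat, s.rest_quat)
            anc = list(ancestors[s.parent])
        sl = tree.joint_slice(s.name)
        for k, (axis, angle) in enumerate(
            zip(s.joint_axes, pose.q[sl])
        ):
            j = sl.start + k
            joint_axis_world[j] = quat_rotate(quat, axis)
            joint_origin_world[j] = pos
            quat = quat_mul(quat, quat_from_axis_angle(axis, angle))
            anc.append(j)
        frames[s.name] = (pos, quat_normalize(quat))
        ancestors[s.name] = anc

    site_map = {st.name: st for st in tree.sites}
    n_sites = len(site_names)
    positions = np.zeros((n_sites, 3))
    jac = np.zeros((n_sites, 3, len(free_joints)))
    col = {j: c for c, j in enumerate(free_joints)}
    for i, name in enumerate(site_names):
        st = site_map[name]
        pos, quat = frames[st.segment]
        p = pos + quat_rotate(quat, st.offset)
        positions[i] = p
        for j in ancestors[st.segment]:
            c = col.get(j)
            if c is not None:
                jac[i, :, c] = np.cross(
                    joint_axis_world[j], p - joint_origin_world[j]
                )
    return positions, jac


def _objective(positions, targets, q, q0, lam):
    r = positions - targets
    return float(np.sum(r * r) + lam * np.sum((q - q0) ** 2))


def fit_frame(
    tree: KinematicTree,
    targets: dict,
    pose_init: Pose | None = None,
    cfg: IKConfig | None = None,
    free_joints=None,
) -> IKResult:
    """Fit one frame of keypoint targets.

    ``targets`` maps site names to world 3-vectors (m).  ``free_joints``
    restricts the optimized joint indices (default: all); the root pose
    is co-optimized when ``cfg.fit_root``.
    """
    cfg = cfg if cfg is not None else IKConfig()
    site_names = list(targets.keys())
    known = {st.name for st in tree.sites}
    unknown = [n for n in site_names if n not in known]
    if unknown:
        raise ContractError(f"targets reference unregistered sites: {unknown}")
    tgt = np.array([targets[n] for n in site_names], dtype=float)
    if free_joints is None:
        free_joints = list(range(tree.n_joints))
    free_joints = list(free_joints)
    q0 = (
        np.zeros(tree.n_joints)
        if cfg.q0 is None
        else np.asarray(cfg.q0, dtype=float)
    )
    pose = (
        tree.zero_pose() if pose_init is None
        else Pose(pose_init.root_position.copy(),
                  pose_init.root_orientation.copy(),
                  pose_init.q.copy())
    ).clamped(tree)
    lims = tree.joint_limits()

    positions, jac = _site_positions_and_jacobian(
        tree, pose, site_names, free_joints
    )
    obj = _objective(positions, tgt, pose.q, q0, cfg.lam)
    if obj <= cfg.abs_tol:
        return IKResult(pose, np.linalg.norm(positions - tgt, axis=1), obj,
                        0, True)
    nq = len(free_joints)
    n_var = nq + (6 if cfg.fit_root else 0)
    mu = 1e-3
    iterations = 0
    converged = False
    for it in range(cfg.max_iter):
        resid = positions - tgt
        # full Jacobian: joint columns, then root translation + rotation
        j_full = np.zeros((len(site_names) * 3, n_var))
        j_full[:, :nq] = jac.reshape(len(site_names) * 3, nq)
        if cfg.fit_root:
            for i in range(len(site_names)):
                j_full[3 * i : 3 * i + 3, nq : nq + 3] = np.eye(3)
                arm = positions[i] - pose.root_position
                # d p / d theta_k = e_k x arm
                j_full[3 * i : 3 * i + 3, nq + 3 : nq + 6] = -_skew(arm)
        r_flat = resid.ravel()
        grad = j_full.T @ r_flat
        grad[:nq] += cfg.lam * (pose.q[free_joints] - q0[free_joints])
        if float(grad @ grad) == 0.0:
            converged = True
            break
        hess = j_full.T @ j_full
        hess[:nq, :nq] += cfg.lam * np.eye(nq)
        diag = np.maximum(np.diag(hess), 1e-9 * max(np.diag(hess).max(), 1e-300))
        accepted = False
        for _ in range(cfg.max_halvings + 1):
            try:
                delta = np.linalg.solve(hess + mu * np.diag(diag), -grad)
            except np.linalg.LinAlgError:
                mu *= 4.0
                continue
            q_new = pose.q.copy()
            q_new[free_joints] = pose.q[free_joints] + cfg.step_size * delta[:nq]
            if cfg.fit_root:
                d_t = cfg.step_size * delta[nq : nq + 3]
                d_r = cfg.step_size * delta[nq + 3 : nq + 6]
                ang = np.linalg.norm(d_r)
                new_quat = (
                    quat_mul(quat_from_axis_angle(d_r, ang),
                             pose.root_orientation)
                    if ang > 0
                    else pose.root_orientation
                )
                cand = Pose(pose.root_position + d_t, new_quat, q_new)
            else:
                cand = Pose(pose.root_position, pose.root_orientation, q_new)
            cand = cand.clamped(tree)
            cand_pos, cand_jac = _site_positions_and_jacobian(
                tree, cand, site_names, free_joints
            )
            cand_obj = _objective(cand_pos, tgt, cand.q, q0, cfg.lam)
            if cand_obj <= obj:
                accepted = True
                break
            mu *= 4.0
        iterations = it + 1
        if not accepted:
            break
        rel_drop = (obj - cand_obj) / max(obj, 1e-300)
        pose, positions, jac, obj = cand, cand_pos, cand_jac, cand_obj
        mu = max(mu / 3.0, 1e-12)
        if rel_drop < cfg.tol or obj <= cfg.abs_tol:
            converged = True
            break
    residuals = np.linalg.norm(positions - tgt, axis=1)
    return IKResult(pose, residuals, obj, iterations, converged)


def fit_trajectory(
    tree: KinematicTree,
    target_sequence: list,
    cfg: IKConfig | None = None,
    free_joints=None,
) -> list:
    """Fit a sequence of frames, warm-starting each from the previous."""
    if not target_sequence:
        raise ContractError("empty target sequence")
    results = []
    pose = None
    for targets in target_sequence:
        res = fit_frame(tree, targets, pose_init=pose, cfg=cfg,
                        free_joints=free_joints)
        results.append(res)
        pose = res.pose
    return results


def fit_leg(
    tree: KinematicTree,
    leg: str,
    five_targets: dict,
    cfg: IKConfig | None = None,
    do_rescale: bool = True,
) -> IKResult:
    """Fit one leg to its five keypoints (four joints plus the tip).

    With ``do_rescale`` the leg's segment lengths are first scaled so the
    model's inter-keypoint distances match the targets' (decoupling size
    mismatch from DoF mismatch); only that leg's DoFs are optimized and
    the root is held fixed.
    """
    cfg = replace(cfg if cfg is not None else IKConfig(), fit_root=False)
    order = [
        f"{leg}_body_coxa", f"{leg}_coxa_femur", f"{leg}_femur_tibia",
        f"{leg}_tibia_tarsus", f"{leg}_tip",
    ]
    missing = [n for n in order if n not in five_targets]
    if missing:
        raise ContractError(f"fit_leg needs targets for {missing}")
    work = tree
    scale = None
    if do_rescale:
        tgt = np.array([five_targets[n] for n in order])
        d_t = np.linalg.norm(np.diff(tgt, axis=0), axis=1)
        if np.any(d_t < 1e-12):
            import logging

            logging.getLogger(__name__).warning(
                "degenerate (coincident) targets; leg rescale skipped"
            )
        else:
            from flysim.body import forward_kinematics

            _, sites = forward_kinematics(tree, tree.zero_pose())
            mdl = np.array([sites[n] for n in order])
            d_m = np.linalg.norm(np.diff(mdl, axis=0), axis=1)
            # one factor per link; the tarsal chain shares the last one
            link_segments = [
                [f"{leg}_femur"], [f"{leg}_tibia"], [f"{leg}_tarsus_1"],
                [f"{leg}_tarsus_2", f"{leg}_tarsus_3", f"{leg}_tarsus_4",
                 f"{leg}_claw"],
            ]
            factors = {}
            ratios = d_t / np.maximum(d_m, 1e-12)
            # link k spans target gap k (body_coxa->coxa_femur is the coxa
            # root offset of the femur segment, etc.)
            for k, segs in enumerate(link_segments[:3]):
                for sname in segs:
                    factors[sname] = float(ratios[k])
            for sname in link_segments[3]:
                factors[sname] = float(ratios[3])
            work = rescale(tree, factors)
            scale = float(np.mean(ratios))
    free = []
    for segname in ("coxa", "femur", "tibia", "tarsus_1", "tarsus_2",
                    "tarsus_3", "tarsus_4"):
        sl = work.joint_slice(f"{leg}_{segname}")
        free.extend(range(sl.start, sl.stop))
    res = fit_frame(work, five_targets, cfg=cfg, free_joints=free)
    res.leg_scale = scale
    return res
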