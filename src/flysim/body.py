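"""Parametric articulated body model of an adult female fruit fly.

The default body is a kinematic tree of 67 rigid segments: 9 axial segments
(head, thorax, 7 abdominal segments), a 4-segment proboscis, 2 antennae,
2 wings, 2 halteres and six 8-segment legs (coxa, femur, tibia, four tarsal
segments and the tarsal claw).  Segment masses are the bench-measured
per-part values (head 0.15 mg, thorax 0.34 mg, abdomen 0.38 mg, 0.0162 mg
per leg, 0.008 mg per wing), which sum to 0.983 mg.

Each joint is built from up to three hinge axes; groups of three hinges
approximate ball joints.  The multi-segment abdomen and tarsi are
tendon-coupled: one scalar drives the whole chain.  The root segment
(thorax) carries an implicit 6-DoF free joint.

Conventions: world frame is right-handed with +z up and gravity along -z;
the body frame has +x from thorax towards the head, +y to the fly's left,
+z dorsal.  Internally everything is SI; serialization uses cm / mg /
degrees (see :func:`save_yaml`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from flysim import units
from flysim.rotations import (
    IDENTITY_QUAT,
    quat_from_axis_angle,
    quat_mul,
    quat_normalize,
    quat_rotate,
)

GEOM_TYPES = ("capsule", "ellipsoid", "sphere", "box")

LEG_NAMES = ("T1_L", "T1_R", "T2_L", "T2_R", "T3_L", "T3_R")
LEG_SEGMENTS = (
    "coxa",
    "femur",
    "tibia",
    "tarsus_1",
    "tarsus_2",
    "tarsus_3",
    "tarsus_4",
    "claw",
)


class ConfigurationError(ValueError):
    """Invalid body configuration (unknown variant, bad site, ...)."""


class ContractError(ValueError):
    """Violated operation precondition (dimension mismatch, bad factor)."""


@dataclass
class GeomSpec:
    """Geometric primitive used for inertia and contact.

    ``size`` semantics: sphere (r,); capsule (r, half_length); ellipsoid
    (a, b, c) semi-axes; box (hx, hy, hz) half-extents.  Metres.
    """

    type: str
    size: tuple

    def __post_init__(self):
        if self.type not in GEOM_TYPES:
            raise ConfigurationError(f"unknown geom type {self.type!r}")
        self.size = tuple(float(s) for s in self.size)
        if any(s < 0 for s in self.size):
            raise ConfigurationError("geom dimensions must be >= 0")

    def volume(self) -> float:
        s = self.size
        if self.type == "sphere":
            return 4.0 / 3.0 * np.pi * s[0] ** 3
        if self.type == "capsule":
            r, hl = s
            return np.pi * r * r * (2 * hl) + 4.0 / 3.0 * np.pi * r**3
        if self.type == "ellipsoid":
            return 4.0 / 3.0 * np.pi * s[0] * s[1] * s[2]
        hx, hy, hz = s
        return 8.0 * hx * hy * hz

    def inertia(self, mass: float) -> np.ndarray:
        """Inertia tensor about the geom centre, uniform density, kg m^2."""
        s = self.size
        if self.type == "sphere":
            i = 0.4 * mass * s[0] ** 2
            return np.diag([i, i, i])
        if self.type == "ellipsoid":
            a, b, c = s
            return np.diag(
                [
                    mass / 5.0 * (b * b + c * c),
                    mass / 5.0 * (a * a + c * c),
                    mass / 5.0 * (a * a + b * b),
                ]
            )
        if self.type == "box":
            hx, hy, hz = s
            return np.diag(
                [
                    mass / 3.0 * (hy * hy + hz * hz),
                    mass / 3.0 * (hx * hx + hz * hz),
                    mass / 3.0 * (hx * hx + hy * hy),
                ]
            )
        # capsule, axis along x: cylinder + two hemispheres, uniform density
        r, hl = s
        v_cyl = np.pi * r * r * 2 * hl
        v_sph = 4.0 / 3.0 * np.pi * r**3
        v = v_cyl + v_sph
        m_cyl = mass * v_cyl / v
        m_sph = mass * v_sph / v
        ix = 0.5 * m_cyl * r * r + 0.4 * m_sph * r * r
        # transverse: cylinder about centre + hemispheres offset at +-hl
        it_cyl = m_cyl * (r * r / 4.0 + hl * hl / 3.0)
        it_sph = m_sph * (0.4 * r * r + hl * hl + 0.75 * hl * r)
        it = it_cyl + it_sph
        return np.diag([ix, it, it])


@dataclass
class SegmentSpec:
    """One rigid segment of the kinematic tree."""

    name: str
    parent: str | None
    joint_axes: np.ndarray  # (k, 3), k in 0..3, unit hinge axes
    joint_limits: np.ndarray  # (k, 2) radians, lo <= hi
    rest_pos: np.ndarray  # (3,) m, translation relative to parent frame
    rest_quat: np.ndarray  # (4,) unit quaternion (w,x,y,z) rel. parent
    mass: float  # kg
    geom: GeomSpec

    def __post_init__(self):
        self.joint_axes = np.atleast_2d(np.asarray(self.joint_axes, dtype=float))
        if self.joint_axes.size == 0:
            self.joint_axes = np.zeros((0, 3))
        self.joint_limits = np.asarray(self.joint_limits, dtype=float).reshape(-1, 2)
        self.rest_pos = np.asarray(self.rest_pos, dtype=float)
        self.rest_quat = quat_normalize(self.rest_quat)
        self.mass = float(self.mass)
        if self.joint_axes.shape[0] != self.joint_limits.shape[0]:
            raise ConfigurationError(
                f"{self.name}: {self.joint_axes.shape[0]} axes but "
                f"{self.joint_limits.shape[0]} limit pairs"
            )
        if self.joint_axes.shape[0] > 3:
            raise ConfigurationError(f"{self.name}: more than 3 hinge axes")
        for a in self.joint_axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-12:
                raise ConfigurationError(f"{self.name}: joint axis not unit norm")
        for lo, hi in self.joint_limits:
            if lo > hi:
                raise ConfigurationError(f"{self.name}: joint limit lo > hi")
        if self.mass < 0:
            raise ConfigurationError(f"{self.name}: negative mass")

    @property
    def n_joints(self) -> int:
        return self.joint_axes.shape[0]


@dataclass
class Site:
    """Named keypoint attached to a segment at a fixed local offset (m)."""

    name: str
    segment: str
    offset: np.ndarray

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)


@dataclass
class KinematicTree:
    """Ordered articulated tree; parents precede children.

    ``tendon_couplings`` are disjoint groups of joint indices driven by one
    shared scalar.  ``frozen_joints`` marks joints excluded from the
    actuated-DoF list (used by the flight/walking variants); frozen joints
    remain part of the tree and of ``q``.
    """

    segments: list[SegmentSpec]
    root: str
    tendon_couplings: list[list[int]] = field(default_factory=list)
    sites: list[Site] = field(default_factory=list)
    frozen_joints: set[int] = field(default_factory=set)

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate segment names")
        self._index = {n: i for i, n in enumerate(names)}
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1 or roots[0].name != self.root:
            raise ConfigurationError("tree must have exactly one root segment")
        seen = set()
        for s in self.segments:
            if s.parent is not None and s.parent not in seen:
                raise ConfigurationError(
                    f"parent {s.parent!r} of {s.name!r} does not precede it"
                )
            seen.add(s.name)
        # joint index layout: concatenation in segment order
        self._joint_offset = {}
        off = 0
        for s in self.segments:
            self._joint_offset[s.name] = off
            off += s.n_joints
        self._n_joints = off
        flat = [j for g in self.tendon_couplings for j in g]
        if len(flat) != len(set(flat)):
            raise ConfigurationError("tendon groups must be disjoint")
        if flat and (min(flat) < 0 or max(flat) >= off):
            raise ConfigurationError("tendon joint index out of range")

    # -- bookkeeping ----------------------------------------------------
    @property
    def n_joints(self) -> int:
        return self._n_joints

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def joint_slice(self, name: str) -> slice:
        off = self._joint_offset[name]
        return slice(off, off + self.segment(name).n_joints)

    def joint_names(self) -> list[str]:
        out = []
        for s in self.segments:
            for k in range(s.n_joints):
                out.append(f"{s.name}[{k}]")
        return out

    def joint_limits(self) -> np.ndarray:
        if self._n_joints == 0:
            return np.zeros((0, 2))
        return np.concatenate(
            [s.joint_limits for s in self.segments if s.n_joints], axis=0
        )

    def actuated_joint_indices(self) -> np.ndarray:
        """Joint indices that are actuated (not frozen) in this variant."""
        return np.array(
            [i for i in range(self._n_joints) if i not in self.frozen_joints],
            dtype=int,
        )

    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    def zero_pose(self) -> "Pose":
        return Pose(np.zeros(3), IDENTITY_QUAT.copy(), np.zeros(self._n_joints))


@dataclass
class Pose:
    """Root pose plus joint-angle vector."""

    root_position: np.ndarray
    root_orientation: np.ndarray  # (w, x, y, z)
    q: np.ndarray

    def __post_init__(self):
        self.root_position = np.asarray(self.root_position, dtype=float)
        self.root_orientation = quat_normalize(self.root_orientation)
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))

    def clamped(self, tree: KinematicTree) -> "Pose":
        """Project joint angles onto the tree's joint limits (idempotent)."""
        lims = tree.joint_limits()
        q = np.clip(self.q, lims[:, 0], lims[:, 1]) if len(lims) else self.q
        return Pose(self.root_position.copy(), self.root_orientation.copy(), q)


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def forward_kinematics(tree: KinematicTree, pose: Pose):
    """World frame (position, quaternion) of every segment, plus sites.

    Frames compose parent-to-child: the child frame is the parent frame
    translated by ``rest_pos``, rotated by ``rest_quat``, then rotated about
    each hinge axis in order by the corresponding joint angle.

    Returns ``(frames, site_positions)`` where ``frames`` maps segment name
    to ``(pos (3,), quat (4,))`` and ``site_positions`` maps site name to a
    world 3-vector.
    """
    if pose.q.shape[0] != tree.n_joints:
        raise ContractError(
            f"pose has {pose.q.shape[0]} joint angles, tree expects {tree.n_joints}"
        )
    frames: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in tree.segments:
        if s.parent is None:
            p_pos, p_quat = pose.root_position, pose.root_orientation
            pos = np.asarray(p_pos, dtype=float).copy()
            quat = quat_normalize(p_quat)
        else:
            p_pos, p_quat = frames[s.parent]
            pos = p_pos + quat_rotate(p_quat, s.rest_pos)
            quat = quat_mul(p_quat, s.rest_quat)
        qs = pose.q[tree.joint_slice(s.name)]
        for axis, angle in zip(s.joint_axes, qs):
            quat = quat_mul(quat, quat_from_axis_angle(axis, angle))
        frames[s.name] = (pos, quat_normalize(quat))
    site_pos = {}
    for site in tree.sites:
        pos, quat = frames[site.segment]
        site_pos[site.name] = pos + quat_rotate(quat, site.offset)
    return frames, site_pos


def total_mass(tree: KinematicTree) -> float:
    """Sum of segment masses, kg."""
    return tree.total_mass()


def com(tree: KinematicTree, pose: Pose) -> np.ndarray:
    """Mass-weighted mean of segment-frame centres, world frame, m."""
    frames, _ = forward_kinematics(tree, pose)
    m_total = tree.total_mass()
    if m_total == 0.0:
        raise ContractError("total mass is zero; CoM undefined")
    acc = np.zeros(3)
    for s in tree.segments:
        acc += s.mass * frames[s.name][0]
    return acc / m_total


def attach_keypoint_sites(tree: KinematicTree, site_defs) -> KinematicTree:
    """Return a copy of the tree with keypoint sites attached.

    ``site_defs`` is an iterable of ``(name, segment, offset_m)``.
    """
    new = copy.deepcopy(tree)
    for name, segment, offset in site_defs:
        if segment not in new:
            raise ConfigurationError(f"site {name!r} on unknown segment {segment!r}")
        new.sites.append(Site(name, segment, np.asarray(offset, dtype=float)))
    return new


def rescale(tree: KinematicTree, factors) -> KinematicTree:
    """Scale segment lengths/offsets; masses are untouched.

    ``factors`` is a positive scalar applied to every segment, or a mapping
    segment name -> positive scalar.  Scaling serves geometry fitting only,
    so masses (and hence the total mass) are conserved.
    """
    if np.isscalar(factors):
        if factors <= 0:
            raise ContractError("rescale factor must be > 0")
        factors = {s.name: float(factors) for s in tree.segments}
    else:
        for v in factors.values():
            if v <= 0:
                raise ContractError("rescale factors must be > 0")
    new = copy.deepcopy(tree)
    for s in new.segments:
        f = factors.get(s.name)
        if f is None:
            continue
        s.rest_pos = s.rest_pos * f
        s.geom = GeomSpec(s.geom.type, tuple(d * f for d in s.geom.size))
    for site in new.sites:
        f = factors.get(site.segment)
        if f is not None:
            site.offset = site.offset * f
    return new


# ---------------------------------------------------------------------------
# default fly
# ---------------------------------------------------------------------------

# printed per-part masses, mg
MASS_MG = {"head": 0.15, "thorax": 0.34, "abdomen": 0.38, "leg": 0.0162, "wing": 0.008}

# abdomen mass split over the 7 abdominal segments (fractions of 0.38 mg),
# tapering towards the tip
_ABDOMEN_FRACTIONS = (0.22, 0.20, 0.18, 0.15, 0.12, 0.08, 0.05)
# leg mass split over the 8 leg segments (mg per segment)
_LEG_SEGMENT_MG = {
    "coxa": 0.003,
    "femur": 0.006,
    "tibia": 0.004,
    "tarsus_1": 0.0007,
    "tarsus_2": 0.0007,
    "tarsus_3": 0.0007,
    "tarsus_4": 0.0007,
    "claw": 0.0004,
}

_AX = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


def _hinge(*axes_limits):
    axes = np.array([_AX[a] for a, _ in axes_limits])
    lims = np.deg2rad([l for _, l in axes_limits])
    return axes, lims


def _cm(*xyz):
    return units.cm_to_m(np.array(xyz, dtype=float))


def build_default_fly(variant: str = "full") -> KinematicTree:
    """Construct the default 67-segment fly body.

    Variants: ``full``; ``flight`` (legs retracted to the flight posture
    and their DoFs frozen, i.e. excluded from the actuated-DoF list);
    ``walking`` (wings folded and frozen).  All variants keep the full
    67-segment composition and 0.983 mg total mass.

    The per-joint DoF layout is a documented approximation (hinge triples
    as ball joints at the neck, wing base and body-coxa; single hinges
    along the leg chain; coupled abdominal/tarsal chains); query it with
    :meth:`KinematicTree.joint_names`.
    """
    if variant not in ("full", "flight", "walking"):
        raise ConfigurationError(f"unknown body variant {variant!r}")

    segs: list[SegmentSpec] = []

    def add(name, parent, axes_limits, pos, geom, mass_mg, quat=None):
        axes, lims = _hinge(*axes_limits) if axes_limits else (np.zeros((0, 3)), np.zeros((0, 2)))
        segs.append(
            SegmentSpec(
                name=name,
                parent=parent,
                joint_axes=axes,
                joint_limits=lims,
                rest_pos=pos,
                rest_quat=IDENTITY_QUAT if quat is None else quat,
                mass=units.mg_to_kg(mass_mg),
                geom=geom,
            )
        )

    # axial chain: thorax is the root (free joint), head forward (+x),
    # abdomen rearward (-x).  Body length ~0.297 cm.
    add("thorax", None, [], _cm(0, 0, 0),
        GeomSpec("ellipsoid", _cm(0.055, 0.045, 0.045)), MASS_MG["thorax"])
    add("head", "thorax", [("x", (-30, 30)), ("y", (-60, 60)), ("z", (-45, 45))],
        _cm(0.085, 0, 0.01), GeomSpec("sphere", _cm(0.030)), MASS_MG["head"])

    # proboscis: 4-segment chain under the head, pitch hinges
    parent = "head"
    for i in range(1, 5):
        add(f"proboscis_{i}", parent, [("y", (-30, 60))],
            _cm(0.012 if i > 1 else 0.015, 0, -0.02 if i == 1 else 0),
            GeomSpec("capsule", _cm(0.004, 0.006)), 0.0)
        parent = f"proboscis_{i}"

    # antennae
    for side, sy in (("L", 1.0), ("R", -1.0)):
        add(f"antenna_{side}", "head", [("z", (-45, 45))],
            _cm(0.025, 0.012 * sy, 0.012),
            GeomSpec("capsule", _cm(0.003, 0.010)), 0.0)

    # abdomen: 7 tapering segments, pitch+yaw each; pitch joints coupled
    parent = "thorax"
    ab_len = (0.030, 0.028, 0.024, 0.020, 0.016, 0.012, 0.010)  # cm half-lengths
    for i in range(1, 8):
        r = 0.040 - 0.004 * i
        add(f"abdomen_{i}", parent, [("y", (-20, 20)), ("z", (-15, 15))],
            _cm(-(ab_len[i - 2] + ab_len[i - 1]) if i > 1 else -0.075, 0, -0.004),
            GeomSpec("capsule", _cm(r, ab_len[i - 1])),
            MASS_MG["abdomen"] * _ABDOMEN_FRACTIONS[i - 1])
        parent = f"abdomen_{i}"

    # wings: slender ellipsoids hinged at the thorax shoulder; span along
    # the local y axis (chord x, thickness z), so stroke = hinge about z,
    # deviation about x, pitch about the span axis y.
    # Half-span 0.1285 cm each => wingspan 4*0.1285 + thorax width 0.09 = 0.604 cm.
    for side, sy in (("L", 1.0), ("R", -1.0)):
        add(f"wing_{side}", "thorax",
            [("z", (-100, 100)), ("x", (-60, 60)), ("y", (-90, 90))],
            _cm(0.005, 0.045 * sy, 0.035),
            GeomSpec("ellipsoid", _cm(0.044, 0.1285, 0.0005)), MASS_MG["wing"])

    # halteres
    for side, sy in (("L", 1.0), ("R", -1.0)):
        add(f"haltere_{side}", "thorax", [("z", (-30, 30))],
            _cm(-0.040, 0.040 * sy, 0.010),
            GeomSpec("sphere", _cm(0.005)), 0.0)

    # legs: 8 segments each; body-coxa ball (3 hinges), single hinges below,
    # tarsal chain coupled by a tendon, claw rigid.
    leg_x = {"T1": 0.045, "T2": 0.0, "T3": -0.045}
    seg_geom = {
        "coxa": ("capsule", (0.008, 0.012)),
        "femur": ("capsule", (0.007, 0.026)),
        "tibia": ("capsule", (0.005, 0.026)),
        "tarsus_1": ("capsule", (0.003, 0.008)),
        "tarsus_2": ("capsule", (0.0028, 0.007)),
        "tarsus_3": ("capsule", (0.0026, 0.006)),
        "tarsus_4": ("capsule", (0.0024, 0.006)),
        "claw": ("sphere", (0.003,)),
    }
    seg_axes = {
        "coxa": [("x", (-60, 60)), ("y", (-60, 60)), ("z", (-60, 60))],
        "femur": [("y", (-150, 30))],
        "tibia": [("y", (-30, 150))],
        "tarsus_1": [("y", (-45, 45))],
        "tarsus_2": [("y", (-45, 45))],
        "tarsus_3": [("y", (-45, 45))],
        "tarsus_4": [("y", (-45, 45))],
        "claw": [],
    }
    for leg in LEG_NAMES:
        pair, side = leg.split("_")
        sy = 1.0 if side == "L" else -1.0
        parent = "thorax"
        for segname in LEG_SEGMENTS:
            gtype, gsize = seg_geom[segname]
            if segname == "coxa":
                pos = _cm(leg_x[pair], 0.042 * sy, -0.030)
            else:
                prev = LEG_SEGMENTS[LEG_SEGMENTS.index(segname) - 1]
                prev_len = 2 * seg_geom[prev][1][-1]
                pos = _cm(0, 0.2 * prev_len * sy, -0.9 * prev_len)
            add(f"{leg}_{segname}", parent, seg_axes[segname], pos,
                GeomSpec(gtype, _cm(*gsize)), _LEG_SEGMENT_MG[segname])
            parent = f"{leg}_{segname}"

    tree = KinematicTree(segments=segs, root="thorax")

    # tendon couplings: abdominal pitch joints; per-leg tarsal chains
    abdomen_pitch = [tree.joint_slice(f"abdomen_{i}").start for i in range(1, 8)]
    couplings = [abdomen_pitch]
    for leg in LEG_NAMES:
        couplings.append(
            [tree.joint_slice(f"{leg}_tarsus_{k}").start for k in range(1, 5)]
        )
    frozen: set[int] = set()
    if variant == "flight":
        for leg in LEG_NAMES:
            for segname in LEG_SEGMENTS:
                sl = tree.joint_slice(f"{leg}_{segname}")
                frozen.update(range(sl.start, sl.stop))
    elif variant == "walking":
        for side in ("L", "R"):
            sl = tree.joint_slice(f"wing_{side}")
            frozen.update(range(sl.start, sl.stop))
    return KinematicTree(
        segments=segs, root="thorax", tendon_couplings=couplings,
        sites=list(tree.sites), frozen_joints=frozen,
    )


def default_walking_sites() -> list[tuple[str, str, np.ndarray]]:
    """The 13 tracked keypoints: 3 head, 3 thorax, abdomen tip, 6 leg tips."""
    defs = [
        ("head_top", "head", _cm(0, 0, 0.030)),
        ("head_left", "head", _cm(0.015, 0.026, 0)),
        ("head_right", "head", _cm(0.015, -0.026, 0)),
        ("thorax_front", "thorax", _cm(0.055, 0, 0)),
        ("thorax_left", "thorax", _cm(0, 0.045, 0)),
        ("thorax_right", "thorax", _cm(0, -0.045, 0)),
        ("abdomen_tip", "abdomen_7", _cm(-0.012, 0, 0)),
    ]
    for leg in LEG_NAMES:
        defs.append((f"tip_{leg}", f"{leg}_claw", _cm(0, 0, -0.003)))
    return defs


def leg_validation_sites(leg: str) -> list[tuple[str, str, np.ndarray]]:
    """Five keypoints of one leg: the four joints plus the tarsal tip."""
    if leg not in LEG_NAMES:
        raise ConfigurationError(f"unknown leg {leg!r}")
    return [
        (f"{leg}_body_coxa", f"{leg}_coxa", np.zeros(3)),
        (f"{leg}_coxa_femur", f"{leg}_femur", np.zeros(3)),
        (f"{leg}_femur_tibia", f"{leg}_tibia", np.zeros(3)),
        (f"{leg}_tibia_tarsus", f"{leg}_tarsus_1", np.zeros(3)),
        (f"{leg}_tip", f"{leg}_claw", _cm(0, 0, -0.003)),
    ]


# ---------------------------------------------------------------------------
# serialization (cm / mg / degrees on disk)
# ---------------------------------------------------------------------------

def tree_to_dict(tree: KinematicTree) -> dict:
    return {
        "root": tree.root,
        "segments": [
            {
                "name": s.name,
                "parent": s.parent,
                "joint_axes": s.joint_axes.tolist(),
                "joint_limits_deg": np.rad2deg(s.joint_limits).tolist(),
                "rest_pos_cm": units.m_to_cm(s.rest_pos).tolist(),
                "rest_quat": s.rest_quat.tolist(),
                "mass_mg": float(units.kg_to_mg(s.mass)),
                "geom": {"type": s.geom.type,
                         "size_cm": units.m_to_cm(np.array(s.geom.size)).tolist()},
            }
            for s in tree.segments
        ],
        "tendon_couplings": [list(map(int, g)) for g in tree.tendon_couplings],
        "sites": [
            {"name": st.name, "segment": st.segment,
             "offset_cm": units.m_to_cm(st.offset).tolist()}
            for st in tree.sites
        ],
        "frozen_joints": sorted(int(j) for j in tree.frozen_joints),
    }


def tree_from_dict(d: dict) -> KinematicTree:
    segs = [
        SegmentSpec(
            name=sd["name"],
            parent=sd["parent"],
            joint_axes=np.array(sd["joint_axes"], dtype=float).reshape(-1, 3),
            joint_limits=np.deg2rad(np.array(sd["joint_limits_deg"], dtype=float)).reshape(-1, 2),
            rest_pos=units.cm_to_m(np.array(sd["rest_pos_cm"], dtype=float)),
            rest_quat=np.array(sd["rest_quat"], dtype=float),
            mass=units.mg_to_kg(sd["mass_mg"]),
            geom=GeomSpec(sd["geom"]["type"],
                          tuple(units.cm_to_m(np.array(sd["geom"]["size_cm"])))),
        )
        for sd in d["segments"]
    ]
    return KinematicTree(
        segments=segs,
        root=d["root"],
        tendon_couplings=[list(g) for g in d.get("tendon_couplings", [])],
        sites=[
            Site(sd["name"], sd["segment"],
                 units.cm_to_m(np.array(sd["offset_cm"], dtype=float)))
            for sd in d.get("sites", [])
        ],
        frozen_joints=set(d.get("frozen_joints", [])),
    )


def save_yaml(tree: KinematicTree, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(tree_to_dict(tree), fh, sort_keys=False)


def load_yaml(path) -> KinematicTree:
    with open(path) as fh:
        return tree_from_dict(yaml.safe_load(fh))
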