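"""Stateless quasi-steady fluid wrench model for ellipsoids.

Approximates five fluid phenomena acting on a rigid ellipsoid moving
through an incompressible quiescent fluid: added mass, viscous (Stokes)
resistance, quadratic drag, Magnus lift and Kutta lift.  Forces and
torques are polynomial in the fluid density ``rho`` and viscosity ``beta``
and in the ellipsoid's shape and body-frame velocities — no wake state is
kept, which is what makes the model cheap enough for whole-body
simulation of a flapping insect.

All component functions work in the ellipsoid's own frame (axes aligned
with the semi-axes, origin at the centre); :func:`total_fluid_wrench_world`
maps world-frame kinematics through an ellipsoid pose.

Formulation (semi-axes ``(a, b, c)``, volume ``V = 4/3 pi a b c``, fluid
density ``rho``, dynamic viscosity ``beta``, body-frame velocity ``v`` and
angular velocity ``w``; dimensionless coefficients
``c = (c_blunt, c_slender, c_angular, c_kutta, c_magnus)``):

* viscous resistance (linear, low Reynolds):
  ``F = -6 pi beta r_D v`` and ``T = -8 pi beta r_D^3 w`` with the
  equivalent radius ``r_D = (a + b + c)/3``; exact Stokes law in the
  sphere limit.
* quadratic drag:
  ``F = -rho |v| [c_blunt A_proj(v) + c_slender max(0, A_max - A_proj(v))] v``
  where ``A_proj(n) = pi sqrt(b^2 c^2 n_x^2 + a^2 c^2 n_y^2 + a^2 b^2 n_z^2)``
  is the projected silhouette area along the motion direction and
  ``A_max`` the largest cross-section; the angular term is
  ``T_i = -rho c_angular |w| w_i I_i`` with the moment factor
  ``I_i = (8/15) pi r_j r_k (r_j^3 + r_k^3)`` built from the two
  semi-axes orthogonal to axis ``i``.
* Magnus lift: ``F = c_magnus rho V (w x v)``.
* Kutta (circulation) lift: with the chord normal ``n`` (unit vector of
  the smallest semi-axis) and planform area ``A_k`` (largest
  cross-section), ``F = c_kutta rho A_k |v|^2 sin(alpha) u`` where
  ``sin(alpha) = v_hat . n`` and ``u = n - sin(alpha) v_hat``; the
  magnitude follows the thin-wing ``sin(alpha) cos(alpha)`` law, zero at
  0 and 90 degrees angle of attack and maximal at 45 degrees, and the
  force is perpendicular to ``v`` in the plane spanned by ``v`` and ``n``.
* added mass: potential-flow virtual inertia with Lamb's coefficients
  ``alpha_i = a b c * (2/3) R_D(r_j^2, r_k^2, r_i^2)`` (Carlson
  integral), translational entries ``rho V alpha_i / (2 - alpha_i)``
  (``rho V / 2`` per axis in the sphere limit) and Lamb's rotational
  entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import elliprd

from flysim.rotations import quat_rotate, quat_conj

#: default dimensionless coefficients (blunt drag, slender drag, angular
#: drag, Kutta lift, Magnus lift) used for the calibrated fly wing
DEFAULT_FLUIDCOEF = (1.0, 0.5, 1.5, 1.7, 1.0)

#: air at 20 degrees C
AIR = None  # set below, after FluidMedium is defined


@dataclass
class EllipsoidGeom:
    """Ellipsoid with semi-axes (a, b, c) m; optional world pose.

    ``span_axis`` indexes the long (span) axis of a wing; the chord
    normal used by the Kutta term is the smallest axis and is derived
    from the shape, not stored.
    """

    semi_axes: tuple
    span_axis: int = 1
    pose_pos: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pose_quat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))

    def __post_init__(self):
        self.semi_axes = tuple(float(s) for s in self.semi_axes)
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be > 0")
        self.pose_pos = np.asarray(self.pose_pos, dtype=float)
        self.pose_quat = np.asarray(self.pose_quat, dtype=float)

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def projected_area(self, direction) -> float:
        """Silhouette area of the ellipsoid projected along a unit vector."""
        a, b, c = self.semi_axes
        n = np.asarray(direction, dtype=float)
        n = n / np.linalg.norm(n)
        return np.pi * np.sqrt(
            (b * c * n[0]) ** 2 + (a * c * n[1]) ** 2 + (a * b * n[2]) ** 2
        )

    @property
    def max_cross_section(self) -> float:
        s = sorted(self.semi_axes)
        return np.pi * s[1] * s[2]

    @property
    def chord_normal(self) -> np.ndarray:
        n = np.zeros(3)
        n[int(np.argmin(self.semi_axes))] = 1.0
        return n


@dataclass
class FluidMedium:
    """Fluid density (kg m^-3) and dynamic viscosity (Pa s)."""

    density: float = 1.204
    viscosity: float = 1.8e-5

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.viscosity < 0:
            raise ValueError("viscosity must be >= 0")


AIR = FluidMedium()


@dataclass
class FluidCoefficients:
    """The five dimensionless coefficients of the phenomenological model."""

    blunt_drag: float = DEFAULT_FLUIDCOEF[0]
    slender_drag: float = DEFAULT_FLUIDCOEF[1]
    angular_drag: float = DEFAULT_FLUIDCOEF[2]
    kutta_lift: float = DEFAULT_FLUIDCOEF[3]
    magnus_lift: float = DEFAULT_FLUIDCOEF[4]

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.blunt_drag, self.slender_drag, self.angular_drag,
             self.kutta_lift, self.magnus_lift]
        )

    @classmethod
    def from_array(cls, arr) -> "FluidCoefficients":
        return cls(*[float(x) for x in arr])


@dataclass
class BodyKinematics:
    """Ellipsoid-frame linear/angular velocity and optional acceleration."""

    v: np.ndarray
    w: np.ndarray
    a_lin: np.ndarray | None = None

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.a_lin is not None:
            self.a_lin = np.asarray(self.a_lin, dtype=float)


@dataclass
class Wrench:
    """Force (N) and torque (N m) about the ellipsoid centre."""

    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torque: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)

    def __add__(self, other: "Wrench") -> "Wrench":
        return Wrench(self.force + other.force, self.torque + other.torque)

    def power(self, kin: BodyKinematics) -> float:
        return float(self.force @ kin.v + self.torque @ kin.w)


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def equivalent_radius(geom: EllipsoidGeom) -> float:
    return sum(geom.semi_axes) / 3.0


def viscous_resistance_wrench(
    geom: EllipsoidGeom, kin: BodyKinematics, medium: FluidMedium
) -> Wrench:
    """Linear (Stokes-like) resistance; exact Stokes law for a sphere."""
    r = equivalent_radius(geom)
    force = -6.0 * np.pi * medium.viscosity * r * kin.v
    torque = -8.0 * np.pi * medium.viscosity * r**3 * kin.w
    return Wrench(force, torque)


def quadratic_drag_wrench(
    geom: EllipsoidGeom,
    kin: BodyKinematics,
    medium: FluidMedium,
    coeffs: FluidCoefficients,
) -> Wrench:
    """High-Reynolds pressure drag: blunt + slender force, angular torque."""
    speed = np.linalg.norm(kin.v)
    force = np.zeros(3)
    if speed > 0:
        a_proj = geom.projected_area(kin.v)
        a_slender = max(0.0, geom.max_cross_section - a_proj)
        force = (
            -medium.density
            * speed
            * (coeffs.blunt_drag * a_proj + coeffs.slender_drag * a_slender)
            * kin.v
        )
    wnorm = np.linalg.norm(kin.w)
    torque = np.zeros(3)
    if wnorm > 0:
        r = geom.semi_axes
        moment = np.array(
            [
                r[1] * r[2] * (r[1] ** 3 + r[2] ** 3),
                r[0] * r[2] * (r[0] ** 3 + r[2] ** 3),
                r[0] * r[1] * (r[0] ** 3 + r[1] ** 3),
            ]
        ) * (8.0 / 15.0) * np.pi
        torque = -medium.density * coeffs.angular_drag * wnorm * moment * kin.w
    return Wrench(force, torque)


def magnus_force(
    geom: EllipsoidGeom,
    kin: BodyKinematics,
    medium: FluidMedium,
    coeffs: FluidCoefficients,
) -> np.ndarray:
    """Spin lift F = c_magnus * rho * V * (w x v)."""
    return coeffs.magnus_lift * medium.density * geom.volume * np.cross(kin.w, kin.v)


def kutta_lift(
    geom: EllipsoidGeom,
    kin: BodyKinematics,
    medium: FluidMedium,
    coeffs: FluidCoefficients,
) -> np.ndarray:
    """Circulation lift of a thin wing at angle of attack.

    Perpendicular to ``v``, in the plane of ``v`` and the chord normal;
    magnitude follows ``sin(alpha) cos(alpha)`` so it vanishes edgewise
    (alpha = 0) and broadside (alpha = 90 deg) and peaks at 45 deg.
    """
    speed = np.linalg.norm(kin.v)
    if speed == 0.0:
        return np.zeros(3)
    v_hat = kin.v / speed
    n = geom.chord_normal
    sin_a = float(v_hat @ n)
    u = n - sin_a * v_hat  # |u| = cos(alpha), u . v = 0
    return (
        coeffs.kutta_lift
        * medium.density
        * geom.max_cross_section
        * speed**2
        * sin_a
        * u
    )


def lamb_coefficients(geom: EllipsoidGeom) -> np.ndarray:
    """Lamb's depolarization factors alpha_i (sum to 2; 2/3 for a sphere)."""
    a, b, c = geom.semi_axes
    sq = np.array([a * a, b * b, c * c])
    abc = a * b * c
    out = np.empty(3)
    for i in range(3):
        j, k = [m for m in range(3) if m != i]
        # int_0^inf ds / ((s + r_i^2) Delta) = (2/3) R_D(r_j^2, r_k^2, r_i^2)
        out[i] = abc * (2.0 / 3.0) * float(elliprd(sq[j], sq[k], sq[i]))
    return out


def added_mass_matrix(geom: EllipsoidGeom, medium: FluidMedium) -> np.ndarray:
    """6x6 symmetric PSD virtual-inertia matrix, ellipsoid frame.

    Rows/columns 0..2 are translation, 3..5 rotation.  Sphere limit:
    translational diagonal = rho V / 2, rotational = 0.
    """
    alpha = lamb_coefficients(geom)
    rho_v = medium.density * geom.volume
    m_trans = rho_v * alpha / (2.0 - alpha)
    sq = np.array([s * s for s in geom.semi_axes])
    i_rot = np.zeros(3)
    for i in range(3):
        j, k = [m for m in range(3) if m != i]
        d2 = sq[j] - sq[k]
        if abs(d2) < 1e-12 * max(sq):
            continue  # symmetric section: no added rotational inertia
        num = d2 * d2 * (alpha[k] - alpha[j])
        den = 2.0 * d2 - (sq[j] + sq[k]) * (alpha[k] - alpha[j])
        val = 0.2 * rho_v * num / den
        i_rot[i] = max(val, 0.0)
    return np.diag(np.concatenate([m_trans, i_rot]))


def added_mass_force(
    geom: EllipsoidGeom, kin: BodyKinematics, medium: FluidMedium
) -> np.ndarray:
    """Reaction force -M_A @ a_lin (zero when no acceleration is given)."""
    if kin.a_lin is None:
        return np.zeros(3)
    m = added_mass_matrix(geom, medium)
    return -m[:3, :3] @ kin.a_lin


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

COMPONENT_NAMES = (
    "viscous_resistance",
    "quadratic_drag",
    "magnus",
    "kutta",
    "added_mass",
)


def total_fluid_wrench(
    geom: EllipsoidGeom,
    kin: BodyKinematics,
    medium: FluidMedium,
    coeffs: FluidCoefficients | None = None,
):
    """Sum of the five components plus a labelled per-component breakdown.

    Returns ``(Wrench, dict[str, Wrench])`` in the ellipsoid frame.
    """
    if coeffs is None:
        coeffs = FluidCoefficients()
    breakdown = {
        "viscous_resistance": viscous_resistance_wrench(geom, kin, medium),
        "quadratic_drag": quadratic_drag_wrench(geom, kin, medium, coeffs),
        "magnus": Wrench(magnus_force(geom, kin, medium, coeffs)),
        "kutta": Wrench(kutta_lift(geom, kin, medium, coeffs)),
        "added_mass": Wrench(added_mass_force(geom, kin, medium)),
    }
    total = Wrench()
    for w in breakdown.values():
        total = total + w
    return total, breakdown


def total_fluid_wrench_world(
    geom: EllipsoidGeom,
    v_world,
    w_world,
    medium: FluidMedium,
    coeffs: FluidCoefficients | None = None,
    a_lin_world=None,
):
    """World-frame wrapper: map kinematics through the ellipsoid pose.

    Rotation equivariant by construction: rotating the pose and the
    world-frame velocities by a common rotation rotates the wrench.
    """
    q_inv = quat_conj(geom.pose_quat)
    kin = BodyKinematics(
        v=quat_rotate(q_inv, v_world),
        w=quat_rotate(q_inv, w_world),
        a_lin=None if a_lin_world is None else quat_rotate(q_inv, a_lin_world),
    )
    local, breakdown = total_fluid_wrench(geom, kin, medium, coeffs)
    q = geom.pose_quat
    world = Wrench(quat_rotate(q, local.force), quat_rotate(q, local.torque))
    world_breakdown = {
        k: Wrench(quat_rotate(q, w.force), quat_rotate(q, w.torque))
        for k, w in breakdown.items()
    }
    return world, world_breakdown
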