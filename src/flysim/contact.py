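"""Coulomb friction with adhesion force injection; static contact resolution.

Contacts obey an elliptic (circular by default) Coulomb cone: a contact
force with normal component ``f_perp >= 0`` and tangential component
``f_par`` sticks iff ``|f_par| <= mu * f_perp``; the cone half-angle is
``atan(mu)`` (45 degrees at the default mu = 1).  An adhesion actuator
injects a controllable force along the inward contact normal — pressing
the foot onto the surface — which raises ``f_perp`` by the injected amount
without changing ``f_par``, thereby enlarging the slip margin
``mu * f_perp - |f_par|``; summed over the feet, adhesion can also hold
the body against gravity on walls and ceilings.

The static solver resolves indeterminate multi-contact equilibria with
the minimum-norm non-negative solution (all contacts share one Lagrange
multiplier; active-set iteration), rather than reproducing a full
constraint-solver.  Per-leg adhesion saturates at one body weight by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flysim import units

#: default static friction coefficient of the fly model
DEFAULT_MU = 1.0
#: one fly body weight in N (0.983 mg under standard gravity)
BODY_WEIGHT_N = 0.983e-6 * units.GRAVITY

#: contacts closer to the surface than this are geometrically active (m)
TOUCH_TOLERANCE = 1e-6


class ContractError(ValueError):
    pass


@dataclass
class ContactPoint:
    """A potential contact: world position, unit outward normal, mu."""

    position: np.ndarray
    normal: np.ndarray
    mu: float = DEFAULT_MU
    #: signed gap to the surface (m); <= TOUCH_TOLERANCE means touching
    gap: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise ContractError("contact normal must be unit length")
        if self.mu < 0:
            raise ContractError("friction coefficient must be >= 0")

    @property
    def active(self) -> bool:
        return self.gap <= TOUCH_TOLERANCE

    def tangent_basis(self) -> np.ndarray:
        """(2, 3) orthonormal basis of the tangent plane."""
        n = self.normal
        ref = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
        t1 = np.cross(n, ref)
        t1 /= np.linalg.norm(t1)
        return np.vstack([t1, np.cross(n, t1)])


@dataclass
class ContactForce:
    """Resolved contact force in the contact's local frame."""

    f_perp: float  # N, along the outward normal, >= 0
    f_par: np.ndarray  # (2,) N in the tangent basis
    slipping: bool = False

    def __post_init__(self):
        self.f_par = np.asarray(self.f_par, dtype=float)
        if self.f_perp < -1e-12:
            raise ContractError("normal contact force must be >= 0")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.f_perp, np.linalg.norm(self.f_par)))


@dataclass
class AdhesionActuator:
    """Adhesion control in [0, 1]; force = control * max_force along -normal."""

    control: float = 0.0
    max_force: float = BODY_WEIGHT_N

    def __post_init__(self):
        if not 0.0 <= self.control <= 1.0:
            raise ContractError("adhesion control must be in [0, 1]")
        if self.max_force < 0:
            raise ContractError("max adhesion force must be >= 0")

    @property
    def force(self) -> float:
        return self.control * self.max_force


def friction_cone_angle(mu: float) -> float:
    """Half-angle of the Coulomb cone in degrees: atan(mu)."""
    if mu < 0:
        raise ContractError("friction coefficient must be >= 0")
    return float(np.rad2deg(np.arctan(mu)))


def slip_margin(force: ContactForce, mu: float) -> float:
    """mu * f_perp - |f_par|; positive strictly inside the cone (N)."""
    return float(mu * force.f_perp - np.linalg.norm(force.f_par))


@dataclass
class ContactSolution:
    """Outcome of a static contact resolution."""

    forces: list  # ContactForce per contact (empty on detachment)
    attached: bool
    any_slipping: bool
    balance_residual: float  # N, ||sum forces + load||

    def margins(self, contacts) -> np.ndarray:
        return np.array(
            [slip_margin(f, c.mu) for f, c in zip(self.forces, contacts)]
        )


def load_scenario_yaml(path):
    """Load a static contact scenario from YAML.

    Schema: ``load_N`` (3-vector), ``contacts`` (list of position_cm,
    normal, mu, gap_cm), ``adhesion`` (optional list of control,
    max_force_N).  Returns ``(load, contacts, adhesion)`` ready for
    :func:`contact_with_adhesion`.
    """
    import yaml

    from flysim import units

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    load = np.asarray(doc["load_N"], dtype=float)
    contacts = [
        ContactPoint(
            position=units.cm_to_m(np.asarray(c["position_cm"], dtype=float)),
            normal=np.asarray(c["normal"], dtype=float),
            mu=float(c.get("mu", DEFAULT_MU)),
            gap=float(units.cm_to_m(c.get("gap_cm", 0.0))),
        )
        for c in doc["contacts"]
    ]
    adhesion = None
    if "adhesion" in doc:
        adhesion = [
            AdhesionActuator(float(a.get("control", 0.0)),
                             float(a.get("max_force_N", BODY_WEIGHT_N)))
            for a in doc["adhesion"]
        ]
    return load, contacts, adhesion


def solution_to_csv(solution: "ContactSolution", contacts, path) -> None:
    """Write per-contact forces and slip margins as CSV."""
    import pandas as pd

    rows = [
        {
            "contact_id": i,
            "fperp_N": f.f_perp,
            "fpar_N": float(np.linalg.norm(f.f_par)),
            "margin_N": slip_margin(f, c.mu),
            "slipping": f.slipping,
        }
        for i, (f, c) in enumerate(zip(solution.forces, contacts))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def contact_with_adhesion(
    load_force,
    contacts: list[ContactPoint],
    adhesion: list[AdhesionActuator] | None = None,
    tol: float = 1e-9,
) -> ContactSolution:
    """Resolve a quasi-static multi-contact scenario with adhesion.

    ``load_force`` is the net external force on the body (N), e.g.
    ``(0, 0, -W)`` for gravity.  Adhesion at contact ``i`` pulls the body
    onto the surface along ``-normal_i`` and raises that contact's normal
    force by the same amount.  The force balance solved is::

        sum_i (f_perp_i n_i + f_par_i) - sum_i a_i n_i + load = 0

    with ``f_perp_i >= 0``.  Among the (generally indeterminate) feasible
    solutions, the minimum-norm one is returned.  If no non-negative
    normal forces can balance the load (pure tension without adhesion),
    the body detaches and ``attached`` is False.  Slip is flagged per
    contact by the cone test ``|f_par| > mu f_perp`` — the scenario is
    then not actually static, and the flag reports that.
    """
    if not contacts:
        raise ContractError("at least one contact is required")
    if adhesion is None:
        adhesion = [AdhesionActuator(0.0) for _ in contacts]
    if len(adhesion) != len(contacts):
        raise ContractError("one adhesion actuator per contact required")

    load = np.asarray(load_force, dtype=float)
    normals = np.array([c.normal for c in contacts])
    # adhesion only engages on geometrically active contacts
    a = np.array(
        [ad.force if c.active else 0.0 for ad, c in zip(adhesion, contacts)]
    )
    required = normals.T @ a - load  # total reaction the contacts must supply

    # minimum-norm solution via the shared-multiplier active-set iteration:
    # f_par_i = P_i lam, f_perp_i = max(0, n_i . lam)
    projs = [np.eye(3) - np.outer(n, n) for n in normals]
    p_sum = sum(projs)
    active = np.ones(len(contacts), dtype=bool)
    lam = np.zeros(3)
    for _ in range(len(contacts) + 2):
        m = p_sum + sum(
            np.outer(n, n) for n, act in zip(normals, active) if act
        )
        lam, *_ = np.linalg.lstsq(m, required, rcond=None)
        new_active = normals @ lam > 0
        if np.array_equal(new_active, active):
            break
        active = new_active

    f_perp = np.maximum(0.0, normals @ lam)
    forces = []
    total = -load.copy() * 0.0
    for i, c in enumerate(contacts):
        basis = c.tangent_basis()
        f_par_vec = projs[i] @ lam
        f_par = basis @ f_par_vec
        fc = ContactForce(float(f_perp[i]), f_par)
        fc.slipping = np.linalg.norm(f_par) > c.mu * f_perp[i] + 1e-15
        forces.append(fc)
        total += f_perp[i] * c.normal + f_par_vec
    residual = float(np.linalg.norm(total - required))
    scale = max(np.linalg.norm(required), np.linalg.norm(load), 1e-30)
    attached = residual <= max(tol, 1e-9 * scale)
    if not attached:
        return ContactSolution([], False, False, residual)
    return ContactSolution(forces, True, any(f.slipping for f in forces), residual)
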