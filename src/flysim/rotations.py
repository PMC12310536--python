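"""Quaternion and rotation utilities.

Quaternions are stored ``(w, x, y, z)`` and renormalized after every
update.  scipy's :class:`~scipy.spatial.transform.Rotation` uses the
``(x, y, z, w)`` order, so the two tiny shims at the bottom convert.
"""

import numpy as np
from scipy.spatial.transform import Rotation

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q):
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def quat_mul(q1, q2):
    """Hamilton product q1 * q2, both (w, x, y, z)."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conj(q):
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotate(q, v):
    """Rotate vector v by unit quaternion q (w, x, y, z)."""
    w = q[0]
    u = np.asarray(q[1:], dtype=float)
    v = np.asarray(v, dtype=float)
    return v + 2.0 * np.cross(u, np.cross(u, v) + w * v)


def quat_from_axis_angle(axis, angle):
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        return IDENTITY_QUAT.copy()
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_to_matrix(q):
    return Rotation.from_quat(wxyz_to_xyzw(q)).as_matrix()


def matrix_to_quat(m):
    return xyzw_to_wxyz(Rotation.from_matrix(m).as_quat())


def quat_geodesic_angle(q1, q2):
    """Geodesic angle (rad) between two unit quaternions: 2*acos(|<q1,q2>|)."""
    d = abs(float(np.dot(quat_normalize(q1), quat_normalize(q2))))
    return 2.0 * np.arccos(min(d, 1.0))


def quat_integrate(q, omega, dt):
    """Integrate body-frame angular velocity omega over dt; renormalizes."""
    angle = np.linalg.norm(omega) * dt
    if angle == 0.0:
        return np.asarray(q, dtype=float).copy()
    dq = quat_from_axis_angle(omega, angle)
    return quat_normalize(quat_mul(q, dq))


def wxyz_to_xyzw(q):
    q = np.asarray(q, dtype=float)
    return np.array([q[1], q[2], q[3], q[0]])


def xyzw_to_wxyz(q):
    q = np.asarray(q, dtype=float)
    return np.array([q[3], q[0], q[1], q[2]])
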