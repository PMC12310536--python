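"""Unit conversions between internal SI and bench units.

Internal computations use SI throughout (m, kg, s, rad, N).  Fly-lab data
and most printed quantities come in centimetres, milligrams, milliseconds
and degrees; the converters here are the only sanctioned way to cross that
boundary.
"""

import numpy as np

CM_PER_M = 100.0
MG_PER_KG = 1e6
MS_PER_S = 1e3

#: Standard gravity, m s^-2, pointing along -z in the world frame.
GRAVITY = 9.81


def cm_to_m(x):
    return np.asarray(x, dtype=float) / CM_PER_M


def m_to_cm(x):
    return np.asarray(x, dtype=float) * CM_PER_M


def mg_to_kg(x):
    return np.asarray(x, dtype=float) / MG_PER_KG


def kg_to_mg(x):
    return np.asarray(x, dtype=float) * MG_PER_KG


def ms_to_s(x):
    return np.asarray(x, dtype=float) / MS_PER_S


def s_to_ms(x):
    return np.asarray(x, dtype=float) * MS_PER_S


def deg_to_rad(x):
    return np.deg2rad(np.asarray(x, dtype=float))


def rad_to_deg(x):
    return np.rad2deg(np.asarray(x, dtype=float))
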