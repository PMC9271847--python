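"""Internal-coordinate geometry helpers (NeRF atom placement).

All lengths are in Angstrom and all angles in degrees at this layer;
conversion to simulation units (nm) happens when topologies are built.
The hot path (``place_atom``) is written with scalar arithmetic: it is
called hundreds of thousands of times during toy-structure assembly.
"""
from __future__ import annotations

import math

import numpy as np

__all__ = ["place_atom", "bond_angle", "dihedral_angle"]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given reference atoms A-B-C, the C-D bond length, the
    B-C-D angle and the A-B-C-D dihedral (natural extension reference frame).
    """
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)

    bc0 = c[0] - b[0]
    bc1 = c[1] - b[1]
    bc2 = c[2] - b[2]
    nbc = math.sqrt(bc0 * bc0 + bc1 * bc1 + bc2 * bc2)
    bc0 /= nbc
    bc1 /= nbc
    bc2 /= nbc
    ab0 = b[0] - a[0]
    ab1 = b[1] - a[1]
    ab2 = b[2] - a[2]
    n0 = ab1 * bc2 - ab2 * bc1
    n1 = ab2 * bc0 - ab0 * bc2
    n2 = ab0 * bc1 - ab1 * bc0
    nn = math.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
    if nn < 1e-10:
        # colinear reference frame: pick an arbitrary perpendicular
        h0, h1, h2 = (0.0, 1.0, 0.0) if abs(bc0) > 0.9 else (1.0, 0.0, 0.0)
        n0 = h1 * bc2 - h2 * bc1
        n1 = h2 * bc0 - h0 * bc2
        n2 = h0 * bc1 - h1 * bc0
        nn = math.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
    n0 /= nn
    n1 /= nn
    n2 /= nn
    m0 = n1 * bc2 - n2 * bc1
    m1 = n2 * bc0 - n0 * bc2
    m2 = n0 * bc1 - n1 * bc0

    d0 = -bond * math.cos(ang)
    d1 = bond * math.sin(ang) * math.cos(dih)
    d2 = bond * math.sin(ang) * math.sin(dih)
    return np.array([c[0] + d0 * bc0 + d1 * m0 + d2 * n0,
                     c[1] + d0 * bc1 + d1 * m1 + d2 * n1,
                     c[2] + d0 * bc2 + d1 * m2 + d2 * n2])


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """A-B-C angle in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed IUPAC dihedral A-B-C-D in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.rad2deg(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang
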