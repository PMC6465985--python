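"""Small 3-D geometry helpers shared across the package.

All positions are numpy arrays of shape (3,) in Cartesian angstroms.
"""
from __future__ import annotations

import numpy as np


def norm(v: np.ndarray) -> float:
    return float(np.linalg.norm(v))


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def torsion_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    u = unit(axis)
    t = np.radians(angle_deg_)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    return np.array([
        [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
        [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
        [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
    ])


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               dist: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF construction: position d with |cd|=dist, angle(b,c,d)=angle and
    dihedral(a,b,c,d)=torsion (degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -dist * np.cos(ang),
        dist * np.sin(ang) * np.cos(tor),
        dist * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (no reflection).

    Returns (R, t) with fixed ~= moving @ R.T + t.
    """
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = cf - r @ cm
    return r, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def tetrahedral_directions(center: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Given two existing substituent positions n1, n2 on a tetrahedral center,
    return the two unit vectors of the remaining bond directions."""
    a = unit(n1 - center)
    b = unit(n2 - center)
    bisector = -unit(a + b)
    perp = unit(np.cross(a, b))
    half = np.radians(109.47 / 2.0)
    d1 = unit(bisector * np.cos(half) + perp * np.sin(half))
    d2 = unit(bisector * np.cos(half) - perp * np.sin(half))
    return d1, d2
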