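"""Low-level vector geometry shared across modules.

All positions are ndarray of shape (3,) or (n, 3) in Angstrom; all angles are
in degrees unless a function name says otherwise.  Rotation matrices act on
column vectors (``R @ v``) and are proper (det = +1).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "angle_between",
    "signed_angle",
    "dihedral",
    "rotation_about_axis",
    "place_atom",
    "kabsch",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalised to unit length; raises on (near-)zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero-length vector")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    ua, ub = unit(a), unit(b)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(ua, ub)), np.dot(ua, ub))))


def signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (degrees, (-180, 180]) from a to b about axis (right-hand rule)."""
    ax = unit(axis)
    ap = a - np.dot(a, ax) * ax
    bp = b - np.dot(b, ax) * ax
    ang = np.degrees(np.arctan2(np.dot(np.cross(ap, bp), ax), np.dot(ap, bp)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3, degrees in (-180, 180] (IUPAC sign)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, unit(b2))
    ang = -float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))
    if ang <= -180.0:
        ang += 360.0
    return ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation of angle_deg about axis."""
    a = unit(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * K + (1.0 - c) * np.outer(a, a)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle_deg
    and dihedral(a,b,c,d) = torsion_deg."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.radians(180.0 - angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(moving: np.ndarray, target: np.ndarray, weights=None):
    """Optimal proper superposition of `moving` onto `target`.

    Returns (R, t, rmsd) with ``R @ moving_i + t ~= target_i`` minimising the
    (weighted) RMSD.  Mirror solutions are rejected by the usual determinant
    sign correction, so R is always a proper rotation.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    Pc = P - cp
    Qc = Q - cq
    H = (Pc * w[:, None]).T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (R @ P.T).T + t - Q
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd
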