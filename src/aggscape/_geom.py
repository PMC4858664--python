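"""Low-level vector geometry shared across modules.

Internal-coordinate atom placement (the NeRF construction), dihedral
angles, and least-squares rigid superposition (Kabsch).  All coordinates
are in Angstrom, all angles in radians unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "kabsch_rotation",
    "superpose",
    "rmsd",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in radians."""
    u = _unit(np.asarray(a, float) - b)
    w = _unit(np.asarray(c, float) - b)
    return float(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0)))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in (-pi, pi] (IUPAC sign)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.arctan2(y, x))
    # map -pi -> +pi so the range is (-pi, pi]
    return np.pi if ang == -np.pi else ang


def place_atom(a, b, c, bond_length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c.

    d is at ``bond_length`` from c, with angle b-c-d = ``angle`` and
    dihedral a-b-c-d = ``torsion``.  Standard NeRF construction.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            -np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred ``mobile`` onto centred ``target``."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superpose ``mobile`` onto ``target``.

    Returns ``(moved, rotation, translation)`` such that
    ``moved = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot = kabsch_rotation(mobile - cm, target - ct)
    trans = ct - cm @ rot.T
    return mobile @ rot.T + trans, rot, trans


def rmsd(a: np.ndarray, b: np.ndarray, superposition: bool = True) -> float:
    """Root-mean-square deviation between two coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have the same shape")
    if superposition:
        a, _, _ = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
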