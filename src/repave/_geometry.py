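"""Small geometry kernels shared across modules.

Everything here works on plain ndarrays; no knowledge of the structural
data model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_matrix",
    "angle_between",
    "dihedral",
    "dihedral_gradient",
    "fibonacci_sphere",
    "superpose_rmsd",
]


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_rad`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in radians (IUPAC sign)."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(-np.arctan2(y, x))


def dihedral_gradient(p1, p2, p3, p4):
    """Dihedral angle (rad) and its gradient w.r.t. the four points.

    Uses the standard analytic expressions (see e.g. molecular-mechanics
    texts); returns ``(phi, (g1, g2, g3, g4))`` with each g a 3-vector
    d(phi)/d(p).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_sq = np.dot(n1, n1)
    n2_sq = np.dot(n2, n2)
    b2_norm = np.linalg.norm(b2)
    if n1_sq < 1e-18 or n2_sq < 1e-18 or b2_norm < 1e-12:
        raise ValueError("degenerate (collinear) dihedral geometry")
    phi = dihedral(p1, p2, p3, p4)
    g1 = -b2_norm / n1_sq * n1
    g4 = b2_norm / n2_sq * n2
    d12 = np.dot(b1, b2) / (b2_norm**2)
    d32 = np.dot(b3, b2) / (b2_norm**2)
    g2 = -(1.0 + d12) * g1 + d32 * g4
    g3 = d12 * g1 - (1.0 + d32) * g4
    return phi, (g1, g2, g3, g4)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (golden-spiral)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD of ``mobile`` onto ``reference`` after optimal
    rigid-body superposition (Kabsch)."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    H = mc.T @ rc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ mc.T).T - rc
    return float(np.sqrt((diff**2).sum() / len(mobile)))
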