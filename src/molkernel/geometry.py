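"""Small geometric utilities: rigid superposition and dihedral angles."""
from __future__ import annotations

import numpy as np


def superpose_rmsd(P: np.ndarray, Q: np.ndarray, allow_improper: bool = True) -> float:
    """Best-fit RMSD between two point sets after centroid alignment.

    Finds the orthogonal transform ``R`` minimizing ``|R P - Q|`` over O(3)
    (``allow_improper=True``) or SO(3) and returns the residual RMSD.  The
    point correspondence is positional: row i of ``P`` matches row i of ``Q``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("point sets must have identical shapes")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, s, Vt = np.linalg.svd(H)
    if allow_improper:
        # max trace over O(3) is the sum of singular values
        trace = s.sum()
    else:
        d = np.sign(np.linalg.det(U @ Vt))
        trace = s[0] + s[1] + d * s[2]
    n = len(P)
    msd = (np.sum(Pc ** 2) + np.sum(Qc ** 2) - 2.0 * trace) / n
    return float(np.sqrt(max(msd, 0.0)))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Raises ``ValueError`` when three consecutive atoms are collinear, which
    leaves the torsion undefined.
    """
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: collinear atoms")
    b1u = b1 / np.linalg.norm(b1)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1u)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (Haar measure via QR)."""
    A = rng.standard_normal((3, 3))
    Qm, R = np.linalg.qr(A)
    Qm = Qm @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm
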