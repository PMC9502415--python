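"""Low-level vector geometry shared by the analysis modules.

All coordinates are in angstroms. Periodic imaging is minimum-image on an
orthorhombic box; a ``box`` of ``None`` disables imaging (the convention used by
the plain-text fixture format when no box is given).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mic_displacements",
    "pairwise_distances",
    "min_pair_distance",
    "angle_deg",
    "dihedral_deg",
    "kabsch_align",
    "principal_axis",
]


def mic_displacements(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors ``d`` (..., 3)."""
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Distance matrix (len(a), len(b)) between two coordinate sets, minimum-image."""
    d = a[:, None, :] - b[None, :, :]
    d = mic_displacements(d, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def min_pair_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    return float(np.min(pairwise_distances(a, b, box)))


def angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroDivisionError("zero-length vector in angle computation")
    c = np.dot(u, v) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, range (-180, 180].

    Praxeolitic formulation: numerically stable, single atan2 call.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return ang


def kabsch_align(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` (n, 3) onto ``reference`` (n, 3).

    Returns the transformed copy of ``mobile``. Unweighted; both sets are
    centered, the optimal rotation is found by SVD with the usual reflection
    guard, and the reference centroid is restored.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return P @ R + cr


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Largest-variance direction of a point cloud (unit vector).

    Raises ValueError when all points coincide within machine precision.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("degenerate point cloud: all points coincide")
    return vt[0]
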