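"""Low-level 3-D geometry: torsion angles and rigid-body superposition.

All angles are in degrees on the half-open interval (-180, 180]; all
coordinates are in Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "UnderdeterminedError",
    "SuperpositionReport",
    "dihedral",
    "kabsch_superpose",
    "rotation_about_axis",
]


class DegenerateGeometryError(ValueError):
    """Raised when a torsion angle is requested for degenerate points."""


class UnderdeterminedError(ValueError):
    """Raised when a superposition problem has no unique solution."""


_EPS = 1e-10


def _wrap_half_open(angle_deg: float) -> float:
    """Map an angle to (-180, 180]; -180 is reported as +180."""
    a = (angle_deg + 180.0) % 360.0 - 180.0
    if a <= -180.0:
        a = 180.0
    return float(a)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, IUPAC sign convention.

    Looking down the p2->p3 axis, the angle is positive when p4 is rotated
    clockwise from p1. Returns degrees in (-180, 180].

    Raises
    ------
    DegenerateGeometryError
        if consecutive points coincide or the three bond vectors do not
        span a plane on either side of the central bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < _EPS:
            raise DegenerateGeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear bond vectors: torsion undefined")
    b2u = b2 / np.linalg.norm(b2)
    # atan2 form is numerically stable near 0 and 180 degrees
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return _wrap_half_open(np.degrees(np.arctan2(y, x)))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for a rotation about an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < _EPS:
        raise DegenerateGeometryError("zero-length rotation axis")
    k = axis / n
    t = np.radians(angle_deg)
    kx = np.array(
        [[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]]
    )
    return np.eye(3) + np.sin(t) * kx + (1.0 - np.cos(t)) * (kx @ kx)


@dataclass(frozen=True)
class SuperpositionReport:
    """Result of a least-squares rigid superposition of B onto A.

    The fitted mapping is ``x_a ~= rotation @ x_b + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    n_iterations: int = 1

    def apply(self, coords) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a, coords_b) -> SuperpositionReport:
    """Optimal proper rotation + translation mapping ``coords_b`` onto
    ``coords_a`` in the least-squares sense (the Kabsch solution).

    Reflections are excluded by correcting the sign of the smallest
    singular direction, so ``det(rotation) == +1`` always.

    Raises
    ------
    UnderdeterminedError
        for fewer than 3 point pairs or a collinear point set, where the
        rotation is not unique.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coords_a and coords_b must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise UnderdeterminedError("need at least 3 point pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinearity check: second principal moment must be non-negligible
    for M in (A0, B0):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] < 1e-8 * max(1.0, s[0]):
            raise UnderdeterminedError("collinear point set: rotation not unique")
    H = B0.T @ A0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A0 - B0 @ R.T
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionReport(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)
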