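"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the torsion oracle
scans rotations about the central bond instead of using vector algebra,
the superposition oracle scans an Euler-angle grid instead of the SVD
solution, and the Fisher oracle enumerates tables with exact rational
arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import minimize

from atdqc.geometry import rotation_about_axis


def scan_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle by scanning rotations of p4 about the p2->p3 axis.

    The reported angle is the rotation that brings p4's off-axis
    component into coincidence with p1's (the cis position), refined
    hierarchically down to 1e-6 degree steps.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    u = p3 - p2
    u = u / np.linalg.norm(u)
    w1 = (p1 - p2) - ((p1 - p2) @ u) * u
    w1 = w1 / np.linalg.norm(w1)

    def resid(theta):
        q = rotation_about_axis(u, -theta) @ (p4 - p3) + p3
        w2 = (q - p3) - ((q - p3) @ u) * u
        return np.linalg.norm(w1 - w2 / np.linalg.norm(w2))

    best = min(np.arange(-180.0, 180.0, 1.0), key=resid)
    for step in (1e-2, 1e-4, 1e-6):
        grid = np.arange(best - 120 * step, best + 120 * step, step)
        best = min(grid, key=resid)
    wrapped = (best + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped <= -180.0 else float(wrapped)


def grid_superpose_rmsd(A, B, coarse_step: float = 20.0) -> float:
    """Least-squares superposition r.m.s.d. by Euler-angle grid search
    with local simplex refinement (no SVD involved)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    ex, ey, ez = np.eye(3)

    def rot(angles):
        a, b, c = angles
        return (
            rotation_about_axis(ez, a)
            @ rotation_about_axis(ey, b)
            @ rotation_about_axis(ez, c)
        )

    def rmsd(angles):
        R = rot(angles)
        d = A0 - B0 @ R.T
        return float(np.sqrt((d * d).sum() / len(A0)))

    grid = np.arange(-180.0, 180.0, coarse_step)
    gridb = np.arange(0.0, 180.0 + 1e-9, coarse_step)
    best = min(
        ((a, b, c) for a in grid for b in gridb for c in grid), key=rmsd
    )
    res = minimize(rmsd, np.array(best), method="Nelder-Mead",
                   options=dict(xatol=1e-8, fatol=1e-12, maxiter=5000))
    return float(res.fun)


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p with exact rational arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def pmf(x: int) -> Fraction:
        return Fraction(comb(c1, x) * comb(n - c1, r1 - x), comb(n, r1))

    p_obs = pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = sum(
        (p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs),
        Fraction(0),
    )
    return float(min(Fraction(1), total))
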