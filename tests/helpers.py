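"""Independent oracles used by the test suite.

These deliberately take different computational routes from the package
implementations they check: quaternion eigen-decomposition instead of SVD
Kabsch, Monte-Carlo surface integration instead of deterministic spiral
points, and the generic four-point dihedral instead of the vector-triple
torsion formula.
"""

from __future__ import annotations

import numpy as np


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the Horn quaternion method."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    m = mob.T @ ref
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    n = mob.shape[0]
    msd = ((mob ** 2).sum() + (ref ** 2).sum() - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def four_point_dihedral_deg(n: np.ndarray, G: np.ndarray, S: np.ndarray) -> float:
    """Torsion via the generic dihedral of points (p+n, p, p+G, p+G+S).

    Uses the textbook projection construction (project the outer bonds onto
    the plane normal to the central bond, then take the signed angle), a
    different route from the vector-triple formula it checks.
    """
    p = np.array([3.0, 4.0, 5.0])
    p0, p1, p2, p3 = p + n, p, p + G, p + G + S
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def monte_carlo_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
                     n_points: int, rng: np.random.Generator) -> np.ndarray:
    """Per-atom SASA by random surface-point integration."""
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    out = np.empty(coords.shape[0])
    for i in range(coords.shape[0]):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + expanded[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(coords.shape[0]):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= expanded[j] ** 2
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return out
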