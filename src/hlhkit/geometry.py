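"""Small vector-geometry helpers shared by the builders and analysers.

All angles are in degrees, all distances in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bond_angle", "dihedral", "place_atom", "fit_axis", "fit_cylinder_axis"]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a new atom D from three reference atoms (NeRF construction).

    D is placed so that \\|C-D\\| = *bond*, angle(B, C, D) = *angle* and
    dihedral(A, B, C, D) = *torsion* (degrees).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def fit_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit line through a set of points: (centroid, unit direction)."""
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    # orient consistently (positive along the dominant coordinate)
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    return centroid, direction


def fit_cylinder_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis of the best-fit circular cylinder through a set of points.

    Minimizes the spread of radial distances about the axis.  More robust
    than a straight line fit for helical point sets (a single helix turn
    biases the principal component toward the helix, not its axis).
    """
    from scipy.optimize import least_squares

    pts = np.asarray(points, float)
    centroid, d0 = fit_axis(pts)
    theta0 = np.arccos(np.clip(d0[2], -1.0, 1.0))
    phi0 = np.arctan2(d0[1], d0[0])

    def unpack(params):
        theta, phi, a, b = params
        d = np.array([np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        seed = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, seed)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        return centroid + a * e1 + b * e2, d

    def residuals(params):
        point, d = unpack(params)
        rel = pts - point
        radial = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
        return radial - radial.mean()

    fit = least_squares(residuals, x0=[theta0, phi0, 0.0, 0.0], method="lm")
    point, direction = unpack(fit.x)
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    return point, direction
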