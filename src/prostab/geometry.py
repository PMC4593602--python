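"""Elementary 3-D geometry used across the package.

All coordinates are ndarray of shape (3,) in Angstrom; all angles are in
degrees unless a function name says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance",
    "angle",
    "dihedral",
    "place_atom",
    "unit",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Unit vector along ``v``.  Raises on a zero vector."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector has no direction")
    return v / n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = unit(np.asarray(a, float) - np.asarray(b, float))
    v = unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in degrees, IUPAC sign convention."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    theta: float,
    chi: float,
) -> np.ndarray:
    """Place a new atom D from three reference positions (NeRF construction).

    D is positioned so that \\|D-c\\| = ``bond``, the angle b-c-D equals
    ``theta`` and the torsion a-b-c-D equals ``chi`` (both in degrees).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta_r = np.radians(theta)
    chi_r = np.radians(chi)
    # local frame at c
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(theta_r),
            np.sin(theta_r) * np.cos(chi_r),
            -np.sin(theta_r) * np.sin(chi_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
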