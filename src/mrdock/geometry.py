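"""Geometry primitives: rotations, internal coordinates, optimal superposition."""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_matrix",
    "rotate_about_axis",
    "bond_angle",
    "dihedral_angle",
    "random_unit_vector",
    "random_point_in_ball",
    "kabsch",
    "rotation_angle_deg",
]


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, right-handed."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis has zero length")
    x, y, z = axis / norm
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def rotate_about_axis(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_rad: float
) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis``."""
    R = rotation_matrix(axis, angle_rad)
    return (coords - origin) @ R.T + origin


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion a-b-c-d in radians, in (-π, π], IUPAC sign convention."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere."""
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def random_point_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    """Uniform point in the closed ball of the given radius (r ~ R u^{1/3})."""
    return random_unit_vector(rng) * radius * rng.uniform() ** (1.0 / 3.0)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t)`` with proper rotation R so that ``mobile @ R.T + t``
    minimizes the RMSD to ``target``.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, in [0, 180] degrees."""
    cosang = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
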