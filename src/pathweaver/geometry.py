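"""Low-level vector geometry: torsions, internal-coordinate placement, superposition.

All angles are in degrees at the API surface (the field's convention for
backbone torsions), coordinates in Angstrom.  The torsion sign follows the
IUPAC convention: looking from atom b to atom c, the torsion a-b-c-d is
positive when d rotates clockwise relative to a.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "torsion",
    "bond_angle",
    "place_atom",
    "rotate_about_axis",
    "superpose",
    "rmsd_after_superposition",
    "rmsd_to_many",
    "wrap_angle",
    "circular_difference",
]


def wrap_angle(angle_deg):
    """Wrap an angle (degrees) into (-180, 180]."""
    wrapped = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) - 180.0
    # mod can yield -180 exactly; the convention keeps +180
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


def circular_difference(a_deg, b_deg):
    """Absolute circular distance between two angles in degrees, in [0, 180]."""
    return np.abs(wrap_angle(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)))


def torsion(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 at vertex p1, in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d so that |cd| = bond, angle(b,c,d) = angle_deg and
    torsion(a,b,c,d) = torsion_deg (NeRF construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    # local displacement in the frame of the last three atoms
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotate_about_axis(points: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate points about the line through `origin` along `axis` (right-hand
    rule) by `angle_deg`.  Rodrigues' formula, vectorised over points."""
    pts = np.asarray(points, dtype=float)
    origin = np.asarray(origin, dtype=float)
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    theta = np.radians(angle_deg)
    v = pts - origin
    cos_t = np.cos(theta)
    sin_t = np.sin(theta)
    rotated = (
        v * cos_t
        + np.cross(np.broadcast_to(k, v.shape), v) * sin_t
        + np.outer(v @ k, k) * (1.0 - cos_t)
    )
    return rotated + origin


def superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-RMSD rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` minimises the RMSD to
    ``coords_a``.  The rotation is proper (det +1, Kabsch algorithm);
    degenerate (e.g. collinear) point sets yield one of the optimal
    rotations.

    Raises
    ------
    ValueError
        If fewer than 3 points are given or the shapes disagree.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate arrays must share an (N, 3) shape, got {a.shape} and {b.shape}")
    if a.shape[0] < 3:
        raise ValueError(f"superposition requires at least 3 points, got {a.shape[0]}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    a_c = a - cen_a
    b_c = b - cen_b
    h = b_c.T @ a_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(flip) @ u.T
    translation = cen_a - rotation @ cen_b
    residual = a_c - b_c @ rotation.T
    rmsd = float(np.sqrt(np.sum(residual * residual) / a.shape[0]))
    return rotation, translation, rmsd


def rmsd_after_superposition(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD of the optimal rigid superposition (convenience wrapper)."""
    return superpose(coords_a, coords_b)[2]


def rmsd_to_many(centered_a: np.ndarray, centered_stack: np.ndarray) -> np.ndarray:
    """Optimal-superposition RMSD of one centered point set against a stack.

    Parameters
    ----------
    centered_a : (N, 3) array, already centered at the origin.
    centered_stack : (M, N, 3) array of centered point sets.

    Uses the singular values of the per-pair cross-covariance, so no
    per-pair Python loop is needed.
    """
    a = np.asarray(centered_a, dtype=float)
    stack = np.asarray(centered_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    n = a.shape[0]
    h = np.einsum("mni,nj->mij", stack, a)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    # for a proper rotation the smallest singular value flips sign when det < 0
    corr = np.where(det < 0.0, s[:, 0] + s[:, 1] - s[:, 2], s.sum(axis=1))
    e0 = np.sum(a * a) + np.einsum("mni,mni->m", stack, stack)
    msd = np.maximum(0.0, (e0 - 2.0 * corr) / n)
    return np.sqrt(msd)
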