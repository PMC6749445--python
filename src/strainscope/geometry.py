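"""Vector-geometry primitives shared by every metric.

All angles are in degrees; signed dihedrals follow the IUPAC convention
(clockwise positive when looking from the second to the third point, so an
eclipsed/cis arrangement is 0 deg and anti/trans is 180 deg) and are wrapped
to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "Plane",
    "angle",
    "dihedral",
    "distance",
    "fit_plane",
    "rotation_about_axis",
    "wrap_angle",
]

# Points closer than this are treated as coincident.
_COINCIDENT_TOL = 1e-12
# Collinearity: cross-product norm below this fraction of the product of the
# segment lengths.
_COLLINEAR_TOL = 1e-10


class GeometryError(ValueError):
    """Degenerate input (coincident or collinear points) for a primitive."""


@dataclass(frozen=True)
class Plane:
    """Least-squares plane through a point cloud.

    Attributes
    ----------
    normal : (3,) unit vector orthogonal to the plane.
    centroid : (3,) centroid of the fitted points (lies on the plane).
    rmsd : root-mean-square perpendicular deviation of the points, in the
        units of the input coordinates.
    """

    normal: np.ndarray
    centroid: np.ndarray
    rmsd: float

    def distance_to(self, point: np.ndarray) -> float:
        """Signed perpendicular distance of *point* from the plane."""
        return float(np.dot(np.asarray(point, dtype=float) - self.centroid, self.normal))


def wrap_angle(value: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = (float(value) + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def distance(p1, p2) -> float:
    return float(np.linalg.norm(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)))


def angle(p1, p2, p3) -> float:
    """Angle at vertex ``p2`` between the rays to ``p1`` and ``p3``, in [0, 180]."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < _COINCIDENT_TOL or n2 < _COINCIDENT_TOL:
        raise GeometryError("angle() requires p1 != p2 and p3 != p2")
    # atan2 form is numerically stable near 0 and 180 deg.
    cross = np.linalg.norm(np.cross(v1, v2))
    dot = float(np.dot(v1, v2))
    return float(np.degrees(np.arctan2(cross, dot)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in (-180, 180]; cis = 0, trans = 180."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n2 = np.linalg.norm(b2)
    if n2 < _COINCIDENT_TOL:
        raise GeometryError("dihedral() requires p2 != p3")
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    if (
        np.linalg.norm(c12) < _COLLINEAR_TOL * np.linalg.norm(b1) * n2
        or np.linalg.norm(c23) < _COLLINEAR_TOL * n2 * np.linalg.norm(b3)
    ):
        raise GeometryError("dihedral() is undefined for collinear bounding triples")
    y = n2 * float(np.dot(b1, c23))
    x = float(np.dot(c12, c23))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def fit_plane(points) -> Plane:
    """Least-squares plane minimizing squared perpendicular distances.

    Uses the SVD of the centred coordinates; the normal is the left-singular
    vector of the smallest singular value. Raises :class:`GeometryError` for
    fewer than three points or a collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("fit_plane() requires at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    # Collinear: second singular value vanishes relative to the first.
    if s[0] < _COINCIDENT_TOL or s[1] / s[0] < _COLLINEAR_TOL:
        raise GeometryError("fit_plane() requires non-collinear points")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    rmsd = float(np.sqrt(np.mean(np.square(centred @ normal))))
    return Plane(normal=normal, centroid=centroid, rmsd=rmsd)


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about *axis* (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < _COINCIDENT_TOL:
        raise GeometryError("rotation axis must be non-zero")
    k = axis / norm
    theta = np.radians(angle_deg)
    kx = np.array(
        [[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]]
    )
    return np.eye(3) + np.sin(theta) * kx + (1.0 - np.cos(theta)) * (kx @ kx)
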