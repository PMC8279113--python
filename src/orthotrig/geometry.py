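"""Reference planes, the reoriented measurement frame, rotation primitives.

The angular measurements are taken in a Cartesian frame built from the
dentition itself:

* an occlusal reference plane ("Plane 1") is the total-least-squares fit
  through the lingual-gingival landmarks of all teeth except second molars
  (a gingival plane is less sensitive to inclination changes and to the
  curves of Spee/Wilson than an incisal/cuspal one);
* a median plane ("Plane 2") perpendicular to Plane 1 fixes the lateral
  axis;
* the frame is right-handed with Z normal to Plane 1 (towards the occlusal
  surfaces), X normal to Plane 2 (lateral), and Y = Z x X (anteroposterior,
  pointing anteriorly).

All angle signs downstream depend on these conventions; they are documented
in the README.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .model_io import ArchModel, LandmarkKind, is_second_molar

__all__ = [
    "Plane",
    "ReferenceFrame",
    "RigidTransform",
    "FrameConfig",
    "fit_plane_lsq",
    "build_reference_frame",
    "to_frame_coords",
    "from_frame_coords",
    "rotation_about_z",
]

#: Relative singular-value threshold below which a point set is treated as
#: collinear (degenerate for plane fitting / registration).
COLLINEARITY_RTOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-15:
        raise DegenerateGeometryError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, float))
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise DegenerateGeometryError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p, float) - self.point, self.normal))

    def project(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        return p - self.signed_distance(p) * self.normal


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p -> R p + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise DegenerateGeometryError("rigid transform has wrong shape")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise DegenerateGeometryError("rotation matrix is a reflection")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (n, 3)."""
        p = np.asarray(points, float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform 'self after other': p -> self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class ReferenceFrame:
    """Origin plus right-handed orthonormal axes (rows X, Y, Z)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, float)
        A = np.asarray(self.axes, float)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("frame axes are not orthonormal")
        if np.linalg.det(A) < 1.0 - 1e-9:
            raise DegenerateGeometryError("frame axes are not right-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)

    @property
    def x_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.axes[2]


@dataclass(frozen=True)
class FrameConfig:
    """Options for building the measurement frame.

    median_plane_mode:
        ``incisor_midpoint`` (default) — the median plane passes through the
        in-plane projections of the central incisors' mesial midpoint and of
        the lingual-gingival centroid; intrinsic to the dentition.
        ``native_xz`` — the median plane is perpendicular to Plane 1 and to
        the scanner's native XZ plane; inherits the export orientation.
    exclude:
        FDI codes excluded from Plane-1 fitting and arch alignment
        (default: the four second molars).
    """

    median_plane_mode: str = "incisor_midpoint"
    exclude: frozenset[int] = frozenset({17, 27, 37, 47})

    def __post_init__(self):
        if self.median_plane_mode not in ("incisor_midpoint", "native_xz"):
            raise ValueError(
                f"unknown median_plane_mode {self.median_plane_mode!r}"
            )
        object.__setattr__(self, "exclude", frozenset(int(t) for t in self.exclude))


def fit_plane_lsq(points, hint=None) -> Plane:
    """Total-least-squares plane through a 3D point set.

    The plane passes through the centroid; its normal is the direction
    minimising the sum of squared orthogonal distances (smallest principal
    direction of the centred set).  ``hint`` (a 3-vector) fixes the
    otherwise arbitrary normal sign: the normal is flipped to have a
    positive dot product with it.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or (near-)collinear points, detected via a
        vanishing second singular value.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < COLLINEARITY_RTOL * s[0]:
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    if hint is not None and np.dot(normal, np.asarray(hint, float)) < 0:
        normal = -normal
    return Plane(centroid, normal)


def build_reference_frame(
    initial: ArchModel, config: FrameConfig | None = None
) -> ReferenceFrame:
    """Build the measurement frame from an (initial) arch model.

    Plane 1 is fit through the lingual-gingival landmarks of all teeth not
    in ``config.exclude`` (default: second molars), its normal oriented
    towards the mean occlusal landmark; Plane 2 is built per
    ``config.median_plane_mode``.  The frame origin is the centroid of the
    lingual-gingival points used.
    """
    config = config or FrameConfig()
    used = [
        t for fdi, t in initial.teeth.items() if fdi not in config.exclude
    ]
    if len(used) < 4:
        raise DegenerateGeometryError(
            "reference frame needs at least 4 non-excluded teeth "
            f"(got {len(used)})"
        )
    lg = np.stack([t[LandmarkKind.LINGUAL_GINGIVAL] for t in used])
    occ = np.stack([t[LandmarkKind.OCCLUSAL] for t in used])
    centroid = lg.mean(axis=0)
    plane1 = fit_plane_lsq(lg, hint=occ.mean(axis=0) - centroid)
    z = plane1.normal

    if config.median_plane_mode == "incisor_midpoint":
        centrals = [t for t in used if t.tooth_id % 10 == 1]
        if len(centrals) != 2:
            raise DegenerateGeometryError(
                "incisor_midpoint median plane needs both central incisors "
                f"(found {len(centrals)})"
            )
        a = 0.5 * (centrals[0][LandmarkKind.MESIAL] + centrals[1][LandmarkKind.MESIAL])
        y = _unit(plane1.project(a) - plane1.project(centroid))
    else:  # native_xz: median plane perpendicular to Plane 1 and native XZ
        x_raw = np.cross(z, np.array([0.0, 1.0, 0.0]))
        if np.linalg.norm(x_raw) < 1e-9:
            raise DegenerateGeometryError(
                "Plane-1 normal is parallel to the native Y axis; "
                "native_xz median plane is undefined"
            )
        y = _unit(np.cross(z, _unit(x_raw)))
        # orient Y anteriorly when the central incisors are available
        centrals = [t for t in used if t.tooth_id % 10 == 1]
        if len(centrals) == 2:
            a = 0.5 * (
                centrals[0][LandmarkKind.MESIAL] + centrals[1][LandmarkKind.MESIAL]
            )
            if np.dot(y, plane1.project(a) - plane1.project(centroid)) < 0:
                y = -y
    x = np.cross(y, z)
    return ReferenceFrame(centroid, np.stack([x, y, z]))


def to_frame_coords(p, frame: ReferenceFrame) -> np.ndarray:
    """Express point(s) in frame coordinates: axes . (p - origin)."""
    p = np.asarray(p, float)
    return (p - frame.origin) @ frame.axes.T


def from_frame_coords(p, frame: ReferenceFrame) -> np.ndarray:
    """Inverse of :func:`to_frame_coords`."""
    p = np.asarray(p, float)
    return p @ frame.axes + frame.origin


def rotation_about_z(angle_deg: float) -> RigidTransform:
    """Right-handed (counter-clockwise about +Z) rotation, zero translation.

    ``rotation_about_z(90)`` maps (0, 1, 0) to (-1, 0, 0).
    """
    a = np.deg2rad(float(angle_deg))
    c, s = np.cos(a), np.sin(a)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return RigidTransform(R, np.zeros(3))
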