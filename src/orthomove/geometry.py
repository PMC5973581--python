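"""Coordinate-free 3D geometry kernel.

Rigid fitting of corresponding point sets (Kabsch), total-least-squares
plane fitting, orthogonal projection, anatomical reference frames, and
in-plane angle measurement.  Every other module builds on these
primitives.

Conventions
-----------
* A *point* is a ``numpy`` array of shape ``(3,)``; point lists are
  arrays of shape ``(n, 3)``.  All coordinates are millimetres.
* Rotations are proper (det = +1): superimposition of two scans of the
  same rigid object is an isometry, so no scaling or reflection is ever
  fitted.
* The anatomical reference frame follows the cephalometric construction
  used throughout the package: the occlusal (transverse) plane is fitted
  to the four molar/incisor crown points, its normal is oriented toward
  PNS so the X axis points superiorly, the Y axis runs posterior to
  anterior within the occlusal plane (toward the projection of ANS), and
  Z completes a right-handed triad (transverse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

#: tolerance used for exact-geometry invariants (orthonormality, residuals)
EXACT_TOL = 1e-9
#: tolerance used to declare a configuration degenerate
DEGENERACY_TOL = 1e-6


def as_point(p) -> np.ndarray:
    """Coerce to a finite ``(3,)`` float array."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


def as_points(points) -> np.ndarray:
    """Coerce to a finite ``(n, 3)`` float array."""
    a = np.asarray(points, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Apply to a single point or an ``(n, 3)`` array of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (``other`` is applied first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def apply_transform(t: RigidTransform, points) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(points)


def _check_nondegenerate_source(src: np.ndarray) -> None:
    """Reject sources on which a rigid fit is underdetermined."""
    distinct = np.unique(np.round(src, 9), axis=0)
    if distinct.shape[0] < 3:
        raise DegenerateGeometryError(
            "rigid fit needs at least 3 distinct source points"
        )
    centered = src - src.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < DEGENERACY_TOL * max(1.0, s[0]):
        raise DegenerateGeometryError("source points are collinear")


def fit_rigid_transform(source, target) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid registration of corresponding points.

    Finds the rotation/translation minimising ``sum ||R s_i + t - t_i||^2``
    via the centroid-subtracted cross-covariance SVD, with the determinant
    sign corrected so the result is always a proper rotation even when the
    unconstrained optimum would be a reflection.

    Returns
    -------
    (transform, fre)
        ``fre`` is the fiducial registration error: the RMS residual
        distance of corresponding points after the fitted transform.
    """
    src = as_points(source)
    tgt = as_points(target)
    if src.shape != tgt.shape:
        raise ValueError(
            f"source and target must match in length ({src.shape[0]} vs {tgt.shape[0]})"
        )
    if src.shape[0] < 3:
        raise ValueError("rigid fit needs at least 3 point pairs")
    _check_nondegenerate_source(src)

    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    cov = (src - c_src).T @ (tgt - c_tgt)
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tr = c_tgt - rot @ c_src
    transform = RigidTransform(rot, tr)
    residual = transform.apply(src) - tgt
    fre = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return transform, fre


@dataclass(frozen=True)
class Plane:
    """The plane ``{p : normal · p = offset}`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,):
            raise ValueError("plane normal must be a 3-vector")
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset) / norm)

    def signed_distance(self, points):
        pts = np.asarray(points, dtype=float)
        return pts @ self.normal - self.offset

    def project(self, points) -> np.ndarray:
        """Orthogonal (nearest-point) projection onto the plane."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts2 = np.atleast_2d(pts)
        out = pts2 - np.outer(pts2 @ self.normal - self.offset, self.normal)
        return out[0] if single else out


def fit_plane(points) -> Plane:
    """Total-least-squares plane through ``points`` (n >= 3).

    Minimises the sum of squared *orthogonal* distances; the solution is
    the plane through the centroid whose normal is the smallest principal
    direction of the centered points.  The normal sign is arbitrary; use
    :func:`orient_normal` to fix it.
    """
    pts = as_points(points)
    if pts.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] < DEGENERACY_TOL * max(1.0, s[0]):
        raise DegenerateGeometryError("plane fit is degenerate: points are collinear")
    normal = vt[2]
    return Plane(normal, float(normal @ centroid))


def orient_normal(plane: Plane, toward) -> Plane:
    """Flip the normal, if needed, so ``toward`` lies on the positive side."""
    p = as_point(toward)
    if plane.signed_distance(p) < 0:
        return Plane(-plane.normal, -plane.offset)
    return plane


def project_to_plane(p, plane: Plane) -> np.ndarray:
    """Functional alias for :meth:`Plane.project`."""
    return plane.project(p)


@dataclass(frozen=True)
class ReferenceFrame:
    """Right-handed orthonormal anatomical frame.

    ``origin`` is the projection of PNS onto the occlusal plane (PNS');
    ``axis_x`` points superiorly (along the occlusal-plane normal, toward
    PNS), ``axis_y`` anteriorly (toward the ANS projection, within the
    occlusal plane) and ``axis_z`` transversely.
    """

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    def __post_init__(self):
        o = as_point(self.origin)
        ax = as_point(self.axis_x)
        ay = as_point(self.axis_y)
        az = as_point(self.axis_z)
        for v in (ax, ay, az):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
                raise ValueError("frame axes must be unit vectors")
        if (
            abs(ax @ ay) > 1e-9
            or abs(ax @ az) > 1e-9
            or abs(ay @ az) > 1e-9
        ):
            raise ValueError("frame axes must be pairwise orthogonal")
        if not np.allclose(np.cross(ax, ay), az, atol=1e-9):
            raise ValueError("frame must be right-handed (axis_z = axis_x x axis_y)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axis_x", ax)
        object.__setattr__(self, "axis_y", ay)
        object.__setattr__(self, "axis_z", az)

    @property
    def basis(self) -> np.ndarray:
        """Axes as rows: ``basis @ v`` gives frame components of vector v."""
        return np.stack([self.axis_x, self.axis_y, self.axis_z])

    def coords(self, points) -> np.ndarray:
        """World point(s) -> frame coordinates (x superior, y anterior, z transverse)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = (np.atleast_2d(pts) - self.origin) @ self.basis.T
        return out[0] if single else out

    def point(self, coords) -> np.ndarray:
        """Frame coordinates -> world point (inverse of :meth:`coords`)."""
        c = np.asarray(coords, dtype=float)
        single = c.ndim == 1
        out = np.atleast_2d(c) @ self.basis + self.origin
        return out[0] if single else out


def frame_coords(p, frame: ReferenceFrame) -> np.ndarray:
    """Functional alias for :meth:`ReferenceFrame.coords`."""
    return frame.coords(p)


def build_reference_frame(
    occlusal_points, ans, pns, tol: float = DEGENERACY_TOL
) -> tuple[ReferenceFrame, Plane, Plane]:
    """Construct the anatomical frame from occlusal and skeletal landmarks.

    Parameters
    ----------
    occlusal_points
        The crown points defining the transverse plane (plane 1): both
        first-molar cusps and both central-incisor edge midpoints.
    ans, pns
        Anterior / posterior nasal spine.

    Returns
    -------
    (frame, plane1, plane2)
        ``plane1`` is the fitted occlusal plane with normal oriented
        toward PNS; ``plane2`` is the sagittal plane through the frame
        origin with normal ``axis_z`` (it contains ANS, PNS and their
        plane-1 projections by construction).

    Raises
    ------
    DegenerateGeometryError
        If PNS lies on plane 1 (no vertical direction) or the projections
        of ANS and PNS coincide (no sagittal direction).
    """
    ans = as_point(ans)
    pns = as_point(pns)
    plane1 = orient_normal(fit_plane(occlusal_points), pns)
    pns_p = plane1.project(pns)
    if np.linalg.norm(pns - pns_p) < tol:
        raise DegenerateGeometryError("PNS lies on the occlusal plane")
    ans_p = plane1.project(ans)
    if np.linalg.norm(ans_p - pns_p) < tol:
        raise DegenerateGeometryError("ANS and PNS project to the same point")
    axis_x = (pns - pns_p) / np.linalg.norm(pns - pns_p)
    axis_y = (ans_p - pns_p) / np.linalg.norm(ans_p - pns_p)
    axis_z = np.cross(axis_x, axis_y)
    frame = ReferenceFrame(pns_p, axis_x, axis_y, axis_z)
    plane2 = Plane(axis_z, float(axis_z @ pns_p))
    return frame, plane1, plane2


def sagittal_axis_angle(
    crown, root, frame: ReferenceFrame, plane1: Plane
) -> tuple[float, float]:
    """Sagittal inclination of a tooth's long axis, in degrees.

    The root tip is first dropped onto the occlusal plane; crown, root and
    that foot point are then projected onto the sagittal plane (frame z is
    discarded).  The returned angle is measured at the projected root tip
    between the ray to the projected crown and the ray to the projected
    foot point — i.e. the tooth axis against the vertical through the
    root, as seen from the side.

    Returns
    -------
    (theta_unsigned, theta_signed)
        ``theta_unsigned`` is the interior angle in [0, 180].
        ``theta_signed`` carries a positive sign when the projected crown
        lies anterior (larger frame y) to the vertical reference line and
        negative when posterior.
    """
    crown = as_point(crown)
    root = as_point(root)
    foot = plane1.project(root)
    c2 = frame.coords(crown)[:2]
    r2 = frame.coords(root)[:2]
    f2 = frame.coords(foot)[:2]
    to_crown = c2 - r2
    to_foot = f2 - r2
    n_crown = np.linalg.norm(to_crown)
    n_foot = np.linalg.norm(to_foot)
    if n_crown < 1e-9 or n_foot < 1e-9:
        raise DegenerateGeometryError(
            "tooth-axis projection collapsed (crown on root or root on plane 1)"
        )
    cosang = np.clip(to_crown @ to_foot / (n_crown * n_foot), -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cosang)))
    # anterior side of the vertical line through the projected root: the
    # in-plane perpendicular of the reference ray with positive y component
    perp = np.array([-to_foot[1], to_foot[0]])
    if perp[1] < 0:
        perp = -perp
    side = float(to_crown @ perp)
    signed = -theta if side < 0 else theta
    return theta, signed
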