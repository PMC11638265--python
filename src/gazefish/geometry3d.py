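"""Camera projection, fish pose handling, and pose-conditioned rectification.

The core geometric idea: a fish's eye region is a small, approximately planar
patch of the head.  Given the 3D pose of the fish and a calibrated pinhole
camera, the patch projects to a perspective-distorted quadrilateral in the
image.  Rotating the fish (virtually) so the patch is parallel to the image
plane and re-projecting gives a second quadrilateral; the 3x3 homography H
mapping one onto the other rectifies the eye crop to a fronto-parallel view,
C = H * I, where I are source and C rectified pixel coordinates.

Conventions: world coordinates are metric with x the flow/streamwise axis,
y the tank-width axis and z vertical; pixel origin is top-left with y down;
angles are degrees.  Fish-local frame: x anterior, y left, z dorsal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .errors import (
    BehindCameraError,
    DegenerateCorrespondenceError,
    EyeOccludedError,
)

__all__ = [
    "CameraModel",
    "FishPose",
    "Homography",
    "project_point",
    "build_homography",
    "eye_region_quad",
    "rectify_eye_crop",
    "warp_image",
    "smooth_pose_sequence",
    "rotation_between",
    "rotation_about_axis",
    "fish_basis",
    "fish_rotation",
    "eye_outward_normal",
    "eye_anchor_position",
]


# ---------------------------------------------------------------------------
# rotation helpers
# ---------------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    k = axis / n
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector ``a`` onto unit vector ``b``."""
    a = np.asarray(a, dtype=float) / np.linalg.norm(a)
    b = np.asarray(b, dtype=float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        return rotation_about_axis(axis, 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1.0 / (1.0 + c))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: ``x_cam = R @ x_world + t``, pixels via focal/principal.

    Parameters
    ----------
    focal_length : float
        Focal length in pixels (square pixels assumed).
    principal_point : (2,) array
        Principal point (u0, v0) in pixels.
    rotation : (3, 3) array
        World-to-camera rotation, orthonormal.
    translation : (3,) array
        World-to-camera translation in meters.
    image_size : (int, int)
        (width, height) in pixels.
    """

    focal_length: float
    principal_point: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    image_size: tuple[int, int]

    def __post_init__(self):
        object.__setattr__(self, "principal_point",
                           np.asarray(self.principal_point, dtype=float))
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        R = self.rotation
        if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation must be 3x3 orthonormal (RtR=I within 1e-9)")
        if not self.focal_length > 0:
            raise ValueError("focal_length must be positive")
        w, h = self.image_size
        u0, v0 = self.principal_point
        if not (0 <= u0 <= w and 0 <= v0 <= h):
            raise ValueError("principal point must lie inside image bounds")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.rotation.T @ self.translation

    @property
    def view_axis(self) -> np.ndarray:
        """Camera forward (+z) axis expressed in world coordinates."""
        return self.rotation.T @ np.array([0.0, 0.0, 1.0])

    def pixel_ray(self, uv: np.ndarray) -> np.ndarray:
        """Unit world-space direction of the ray through pixel ``uv``."""
        u, v = np.asarray(uv, dtype=float)
        d_cam = np.array([(u - self.principal_point[0]) / self.focal_length,
                          (v - self.principal_point[1]) / self.focal_length,
                          1.0])
        d = self.rotation.T @ d_cam
        return d / np.linalg.norm(d)


@dataclass
class FishPose:
    """Per-frame state of one fish: rigid pose, bend angles, deformed mesh.

    ``mesh_vertices`` are in world coordinates (meters).  ``eye_anchor_left`` /
    ``eye_anchor_right`` index the vertex at each eye's sclera center.
    ``eye_normal_left/right`` are the rest-frame outward optical axes of the
    eyes (unit vectors in the fish-local frame, by default +/-60 degrees of
    azimuth off the anterior axis).
    """

    frame_index: int
    position: np.ndarray
    heading: np.ndarray
    roll: float
    bone_yaws: np.ndarray
    bone_rolls: np.ndarray
    mesh_vertices: np.ndarray
    mesh_faces: np.ndarray | None
    eye_anchor_left: int
    eye_anchor_right: int
    eye_diameter: float  # mm
    eye_normal_left: np.ndarray = field(
        default_factory=lambda: np.array([0.5, np.sqrt(3) / 2, 0.0]))
    eye_normal_right: np.ndarray = field(
        default_factory=lambda: np.array([0.5, -np.sqrt(3) / 2, 0.0]))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(self.heading)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("heading must be a unit vector")
        self.heading = self.heading / n
        self.bone_yaws = np.asarray(self.bone_yaws, dtype=float)
        self.bone_rolls = np.asarray(self.bone_rolls, dtype=float)
        self.mesh_vertices = np.asarray(self.mesh_vertices, dtype=float)
        if self.eye_diameter <= 0:
            raise ValueError("eye_diameter must be positive (mm)")
        if self.mesh_vertices.shape[0] >= 4:
            # non-coplanarity: rank of centered vertices must be 3
            c = self.mesh_vertices - self.mesh_vertices.mean(axis=0)
            if np.linalg.matrix_rank(c, tol=1e-12) < 3:
                raise ValueError("mesh must have >= 4 non-coplanar vertices")
        else:
            raise ValueError("mesh must have >= 4 vertices")

    @property
    def eye_radius_m(self) -> float:
        return self.eye_diameter * 1e-3 / 2.0


def fish_basis(pose: FishPose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (forward, left, up) unit vectors of the fish-local frame.

    Up starts as world-z projected off the heading, then rolls about the
    heading by ``pose.roll`` (positive roll drops the right flank).
    """
    f = pose.heading
    z = np.array([0.0, 0.0, 1.0])
    u0 = z - np.dot(z, f) * f
    n = np.linalg.norm(u0)
    if n < 1e-9:  # fish pointing straight up/down: use x as dorsal seed
        u0 = np.array([1.0, 0.0, 0.0]) - f[0] * f
        n = np.linalg.norm(u0)
    u0 /= n
    u = rotation_about_axis(f, pose.roll) @ u0
    left = np.cross(u, f)
    return f, left / np.linalg.norm(left), u


def fish_rotation(pose: FishPose) -> np.ndarray:
    """Rotation matrix mapping fish-local vectors (x fwd, y left, z up) to world."""
    f, l, u = fish_basis(pose)
    return np.column_stack([f, l, u])


def eye_anchor_position(pose: FishPose, eye_side: str) -> np.ndarray:
    idx = pose.eye_anchor_left if eye_side == "left" else pose.eye_anchor_right
    return pose.mesh_vertices[idx]


def eye_outward_normal(pose: FishPose, eye_side: str) -> np.ndarray:
    """World-frame outward optical axis of the requested eye at rest."""
    rest = pose.eye_normal_left if eye_side == "left" else pose.eye_normal_right
    n = fish_rotation(pose) @ np.asarray(rest, dtype=float)
    return n / np.linalg.norm(n)


@dataclass(frozen=True)
class Homography:
    """3x3 projective map between pixel planes, normalized so H[2,2] = 1."""

    matrix: np.ndarray
    source_quad: np.ndarray | None = None
    target_quad: np.ndarray | None = None

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(M[2, 2]) < 1e-12 or not np.isfinite(M).all():
            raise DegenerateCorrespondenceError("homography not normalizable")
        M = M / M[2, 2]
        if abs(np.linalg.det(M)) < 1e-12:
            raise DegenerateCorrespondenceError("homography is singular")
        object.__setattr__(self, "matrix", M)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) or (2,) pixel points through H (dehomogenized)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ph = np.hstack([p, np.ones((p.shape[0], 1))])
        q = ph @ self.matrix.T
        out = q[:, :2] / q[:, 2:3]
        return out[0] if np.asarray(points).ndim == 1 else out

    @property
    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix),
                          source_quad=self.target_quad,
                          target_quad=self.source_quad)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def project_point(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project world point(s) (meters) to pixel coordinates.

    Accepts a single (3,) point or an (N, 3) array.  Raises
    :class:`BehindCameraError` if any point has non-positive camera depth.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    pc = p @ camera.rotation.T + camera.translation
    depth = pc[:, 2]
    if np.any(depth <= 0):
        raise BehindCameraError("point(s) at non-positive depth")
    uv = camera.principal_point + camera.focal_length * pc[:, :2] / depth[:, None]
    return uv[0] if single else uv


def _collinearity(quad: np.ndarray) -> float:
    """Smallest doubled-triangle area over all point triples, scale-normalized."""
    q = np.asarray(quad, dtype=float)
    scale = max(np.ptp(q, axis=0).max(), 1e-12)
    areas = []
    from itertools import combinations
    for i, j, k in combinations(range(4), 3):
        v1, v2 = q[j] - q[i], q[k] - q[i]
        areas.append(abs(v1[0] * v2[1] - v1[1] * v2[0]) / scale**2)
    return min(areas)


def build_homography(source_quad: np.ndarray, target_quad: np.ndarray) -> Homography:
    """Estimate the homography mapping 4 source points to 4 target points.

    Uses the normalized direct linear transform (points centered and scaled
    before solving) for numerical stability.  Raises
    :class:`DegenerateCorrespondenceError` on (near-)collinear quads.
    """
    src = np.asarray(source_quad, dtype=float).reshape(4, 2)
    dst = np.asarray(target_quad, dtype=float).reshape(4, 2)
    if _collinearity(src) < 1e-9 or _collinearity(dst) < 1e-9:
        raise DegenerateCorrespondenceError("3 (near-)collinear points in a quad")
    # skimage's estimator implements the normalized DLT
    try:
        tf = ProjectiveTransform.from_estimate(src, dst)
        ok = bool(tf)
    except AttributeError:  # scikit-image < 0.26
        tf = ProjectiveTransform()
        ok = tf.estimate(src, dst)
    if not ok or not np.isfinite(tf.params).all():
        raise DegenerateCorrespondenceError("homography estimation failed")
    return Homography(tf.params, source_quad=src, target_quad=dst)


def eye_region_quad(
    pose: FishPose,
    eye_side: str,
    camera: CameraModel,
    scale: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Source/target quadrilaterals of the eye-tangent rectangle.

    A square of side ``scale * eye_diameter`` lies in the plane tangent to the
    head at the eye anchor, with axes along the local anteroposterior and
    dorsoventral directions.  The source quad is its projection in the current
    pose; the target quad is its projection after rotating the fish (about the
    anchor) so the tangent plane is parallel to the image plane.

    Raises :class:`EyeOccludedError` when the outward eye normal does not face
    the camera.
    """
    if eye_side not in ("left", "right"):
        raise ValueError("eye_side must be 'left' or 'right'")
    anchor = eye_anchor_position(pose, eye_side)
    n = eye_outward_normal(pose, eye_side)
    view = anchor - camera.center
    view = view / np.linalg.norm(view)
    if np.dot(n, view) >= 0:
        raise EyeOccludedError(f"{eye_side} eye faces away from camera")

    f, _, _ = fish_basis(pose)
    a1 = f - np.dot(f, n) * n            # anteroposterior, in tangent plane
    a1 = a1 / np.linalg.norm(a1)
    a2 = np.cross(n, a1)                 # dorsoventral-ish, completes the frame
    s = scale * pose.eye_diameter * 1e-3
    # order: TL, TR, BR, BL in crop coordinates (+x anterior, +y ventral)
    corners = np.array([
        anchor - (s / 2) * a1 + (s / 2) * a2,
        anchor + (s / 2) * a1 + (s / 2) * a2,
        anchor + (s / 2) * a1 - (s / 2) * a2,
        anchor - (s / 2) * a1 - (s / 2) * a2,
    ])
    source_quad = project_point(camera, corners)

    # rotate about the anchor so n aligns with the camera's backward axis,
    # making the tangent plane parallel to the image plane
    R = rotation_between(n, -camera.view_axis)
    rotated = (corners - anchor) @ R.T + anchor
    target_quad = project_point(camera, rotated)
    return source_quad, target_quad


def rectify_eye_crop(
    image: np.ndarray,
    pose: FishPose,
    eye_side: str,
    camera: CameraModel,
    crop_size: int = 160,
    scale: float = 3.0,
    cval: float = 0.0,
) -> tuple[np.ndarray, Homography]:
    """Warp the eye region to a fronto-parallel square crop.

    Returns ``(crop, H)`` where H maps original-image pixels to crop pixels;
    crop +x is the fish's anterior direction, +y ventral.  The metric scale of
    the crop is uniform: ``scale * eye_diameter`` mm across ``crop_size`` px.
    """
    source_quad, _ = eye_region_quad(pose, eye_side, camera, scale=scale)
    S = float(crop_size - 1)
    canonical = np.array([[0.0, 0.0], [S, 0.0], [S, S], [0.0, S]])
    h = build_homography(source_quad, canonical)
    crop = warp_image(image, h, (crop_size, crop_size), cval=cval)
    return crop, h


def warp_image(
    image: np.ndarray,
    h: Homography,
    output_size: tuple[int, int],
    cval: float = 0.0,
) -> np.ndarray:
    """Apply homography ``h`` to ``image`` (bilinear, constant fill).

    ``output_size`` is (width, height).  Output pixel (x, y) is sampled from
    the source at ``H^-1 (x, y, 1)``.
    """
    w, hgt = output_size
    tf = ProjectiveTransform(matrix=h.matrix)
    out = warp(
        np.asarray(image, dtype=float),
        tf.inverse,
        output_shape=(hgt, w),
        order=1,
        cval=cval,
        preserve_range=True,
        clip=False,
    )
    return out


def smooth_pose_sequence(poses: Sequence[FishPose], window: int) -> list[FishPose]:
    """Centered moving-average smoother over a pose sequence.

    Positions, mesh vertices, headings (renormalized), roll and bone angles
    are averaged over a centered window; at the sequence edges the window
    shrinks symmetrically.  ``window`` must be odd and >= 1; window=1 is the
    identity.  This is a deterministic stand-in for a learned temporal
    smoother, adequate at 90 fps where pose changes are small between frames.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return list(poses)
    half = window // 2
    n = len(poses)
    out = []
    for i in range(n):
        r = min(half, i, n - 1 - i)  # shrink symmetrically at edges
        sl = poses[i - r:i + r + 1]
        pos = np.mean([p.position for p in sl], axis=0)
        verts = np.mean([p.mesh_vertices for p in sl], axis=0)
        head = np.mean([p.heading for p in sl], axis=0)
        head = head / np.linalg.norm(head)
        roll = float(np.mean([p.roll for p in sl]))
        yaws = np.mean([p.bone_yaws for p in sl], axis=0)
        rolls = np.mean([p.bone_rolls for p in sl], axis=0)
        out.append(replace(poses[i], position=pos, mesh_vertices=verts,
                           heading=head, roll=roll, bone_yaws=yaws,
                           bone_rolls=rolls))
    return out
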