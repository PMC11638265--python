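"""Retinal-view reconstruction through a wide-FOV virtual eye camera.

A virtual camera sits at the retina center (one eye radius beneath the
sclera surface, i.e. at the eyeball center) and looks along the gaze ray
toward the pupil.  Its field of view is 190 degrees, matching a goldfish
eye; with the two eyes' optical axes at +/-60 degrees of azimuth from the
heading this leaves exactly a 50 degree un-imaged sector behind the fish.

The projection is the equidistant fisheye model: a point at angle theta off
the optical axis lands at radial image distance r = image_radius * theta /
(fov/2), azimuth preserved.  It is radially monotone and invertible over
the full hemisphere-plus, which a pinhole model is not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import polygon as draw_polygon

from .errors import DegenerateGazeError
from .eye_tracker import EyeState, GazeRay
from .geometry3d import FishPose, fish_basis

__all__ = [
    "RetinaCamera",
    "RetinalProjection",
    "place_retina_camera",
    "fisheye_project",
    "render_neighbor",
    "control_conditions",
    "rear_blind_sector_deg",
]


@dataclass(frozen=True)
class RetinaCamera:
    """Virtual eye camera: origin at the retina center, equidistant fisheye."""

    origin: np.ndarray
    optical_axis: np.ndarray
    up_vector: np.ndarray
    fov: float = 190.0
    image_radius: float = 256.0

    def __post_init__(self):
        ax = np.asarray(self.optical_axis, dtype=float)
        up = np.asarray(self.up_vector, dtype=float)
        if not 0 < self.fov < 360:
            raise ValueError("fov must be in (0, 360) degrees")
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise DegenerateGazeError("zero optical axis")
        object.__setattr__(self, "optical_axis", ax / n)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "up_vector", up / np.linalg.norm(up))


@dataclass
class RetinalProjection:
    """Neighbor position on the retinal image for one frame and condition."""

    frame_index: int
    neighbor_id: int
    x: float
    y: float
    visible: bool
    condition: str = "tracked"


def place_retina_camera(eye: EyeState | GazeRay, pose: FishPose,
                        fov: float = 190.0,
                        image_radius: float = 256.0) -> RetinaCamera:
    """Build the retinal camera for one frame from the gaze and the pose.

    Origin and axis come from the gaze ray (retina center -> pupil); the up
    vector is the fish's dorsal axis made orthogonal to the axis, so the
    retinal image rolls with the body as a real eye would.
    """
    if isinstance(eye, GazeRay):
        gaze = eye
    else:
        from .eye_tracker import gaze_from_eye

        gaze = gaze_from_eye(eye, pose)
    _, _, dorsal = fish_basis(pose)
    up = dorsal - np.dot(dorsal, gaze.direction) * gaze.direction
    n = np.linalg.norm(up)
    if n < 1e-9:  # gaze along the dorsal axis: fall back to the heading
        f, _, _ = fish_basis(pose)
        up = f - np.dot(f, gaze.direction) * gaze.direction
        n = np.linalg.norm(up)
    return RetinaCamera(origin=gaze.origin, optical_axis=gaze.direction,
                        up_vector=up / n, fov=fov, image_radius=image_radius)


def fisheye_project(cam: RetinaCamera, point: np.ndarray):
    """Equidistant fisheye projection of world point(s).

    Returns ``(x, y)`` retinal coordinates (px, +x to the camera's right,
    +y toward its up vector) or ``None`` when the point lies outside the
    field of view.  For an (N, 3) input returns an (N, 2) array and an (N,)
    visibility mask.  Raises on a point coincident with the origin.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    d = p - cam.origin
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGazeError("point at the camera origin")
    d = d / norms[:, None]
    cosang = np.clip(d @ cam.optical_axis, -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    visible = theta <= cam.fov / 2.0
    right = np.cross(cam.optical_axis, cam.up_vector)
    xc = d @ right
    yc = d @ cam.up_vector
    az = np.arctan2(yc, xc)
    r = cam.image_radius * theta / (cam.fov / 2.0)
    xy = np.column_stack([r * np.cos(az), r * np.sin(az)])
    if single:
        return (float(xy[0, 0]), float(xy[0, 1])) if visible[0] else None
    return xy, visible


def render_neighbor(cam: RetinaCamera, neighbor_vertices: np.ndarray,
                    neighbor_faces: np.ndarray | None = None,
                    frame_index: int = 0, neighbor_id: int = 1,
                    condition: str = "tracked",
                    raster: bool = False):
    """Project a neighbor's mesh onto the retina.

    The reported retinal position is the centroid of the visible projected
    vertices.  With ``raster=True`` also returns a silhouette image of side
    ``2*image_radius + 1`` px filled triangle-by-triangle in painter's order
    (far to near), origin at the image center, y up.
    """
    V = np.asarray(neighbor_vertices, dtype=float)
    if V.size == 0:
        raise ValueError("neighbor mesh is empty")
    xy, vis = fisheye_project(cam, V)
    proj = RetinalProjection(frame_index=frame_index, neighbor_id=neighbor_id,
                             x=float("nan"), y=float("nan"),
                             visible=bool(vis.any()), condition=condition)
    if proj.visible:
        proj.x = float(xy[vis, 0].mean())
        proj.y = float(xy[vis, 1].mean())
    if not raster:
        return proj
    R = int(cam.image_radius)
    img = np.zeros((2 * R + 1, 2 * R + 1), dtype=np.uint8)
    if neighbor_faces is not None and proj.visible:
        dist = np.linalg.norm(V - cam.origin, axis=1)
        faces = np.asarray(neighbor_faces)
        ok = vis[faces].all(axis=1)
        order = np.argsort(-dist[faces].mean(axis=1))
        for fi in order:
            if not ok[fi]:
                continue
            tri = xy[faces[fi]]
            rr, cc = draw_polygon(R - tri[:, 1], R + tri[:, 0], shape=img.shape)
            img[rr, cc] = 255
    return proj, img


def control_conditions(eye_track: list[EyeState], mode: str,
                       rng_seed: int = 0,
                       max_offset: float = 0.45) -> list[EyeState]:
    """Replace tracked pupil positions by a control condition.

    ``static`` pins the pupil to the sclera center every frame; ``random``
    draws the pupil uniformly over the admissible sclera interior (offset
    magnitude <= ``max_offset``), seeded.  3D pupil points are recomputed
    from the new offsets by the callers that need them.
    """
    if mode not in ("static", "random"):
        raise ValueError("mode must be 'static' or 'random'")
    if not eye_track:
        raise ValueError("empty eye track")
    rng = np.random.default_rng(rng_seed)
    out = []
    for st in eye_track:
        if mode == "static":
            off = np.zeros(2)
        else:
            while True:  # uniform over the admissible disc by rejection
                off = rng.uniform(-max_offset, max_offset, size=2)
                if np.linalg.norm(off) <= max_offset:
                    break
        new = replace(st, normalized_offset=off,
                      view_angle=float(np.degrees(np.arcsin(
                          np.clip(2 * np.linalg.norm(off), 0, 1)))))
        out.append(new)
    return out


def rear_blind_sector_deg(eye_azimuth_deg: float = 60.0,
                          fov: float = 190.0) -> float:
    """Angular width of the horizontal sector imaged by neither eye.

    Each eye covers ``fov`` centered on its optical axis at
    ``+/-eye_azimuth_deg`` from the heading; the rear gap is what remains of
    the circle behind the fish (clamped at 0 when the eyes wrap around).
    """
    half = fov / 2.0
    rear_edge = eye_azimuth_deg + half  # most rearward imaged azimuth
    return max(0.0, 360.0 - 2.0 * rear_edge)
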