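"""Synthetic ground-truth generators: single eye images and two-camera scenes.

The eye-image generator reproduces the validation recipe used to benchmark
the detector: a w x w square filled with a background gray, a light sclera
disk of diameter 2w/3 at the center, a dark pupil disk with radius uniform in
[w/6 - w/20, w/6 + w/20] px and center uniform in [w/2 - w/6, w/2 + w/6] px
per axis (resampled until the pupil lies fully inside the sclera), a random
perspective tilt, a Gaussian blur with kernel size w/6, and single-pixel
white noise dots amounting to 0.05% of the pixel count.

The scene generator builds a full two-fish, two-camera flow-tank recording
with known poses and gaze, used for end-to-end tests: a leader and a follower
hold station against the flow inside the 0.88 x 0.25 x 0.25 m arena, the
leader oscillates laterally, and the follower's eye fixates the leader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .errors import OutOfArenaError, PitchForbiddenError, WTooSmallError
from .geometry3d import (
    CameraModel,
    FishPose,
    Homography,
    eye_anchor_position,
    eye_outward_normal,
    fish_rotation,
    project_point,
    rotation_about_axis,
    warp_image,
)

__all__ = [
    "Circle",
    "SynthEyeRecord",
    "synthesize_eye_image",
    "Skeleton",
    "lbs_deform",
    "make_fish_mesh",
    "SceneConfig",
    "SynthScene",
    "synthesize_scene",
]

ARENA_SIZE = np.array([0.88, 0.25, 0.25])  # test-arena dimensions, meters


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates: center (cx, cy) and diameter, px."""

    cx: float
    cy: float
    diameter: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy])

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


# ---------------------------------------------------------------------------
# synthesized eye images
# ---------------------------------------------------------------------------

@dataclass
class SynthEyeRecord:
    """One synthesized eye image with its ground truth.

    ``true_sclera``/``true_pupil`` are in pre-tilt (canonical) coordinates;
    ``tilt_homography`` maps pre-tilt pixels to the emitted (tilted) image, so
    the post-tilt truth is obtained by transporting the centers through it.
    """

    image: np.ndarray
    w: int
    true_sclera: Circle
    true_pupil: Circle
    tilt_homography: Homography
    noise_count: int
    blur_kernel: int
    background: float
    seed: int | None = None

    @property
    def true_offset(self) -> np.ndarray:
        """Ground-truth normalized pupil offset (pre-tilt frame)."""
        return (self.true_pupil.center - self.true_sclera.center) / self.true_sclera.diameter


def _tilt_homography(w: int, yaw_deg: float, roll_deg: float,
                     focal_factor: float = 2.0) -> Homography:
    """Center-preserving perspective tilt of the image plane.

    The image is treated as a planar card rotated in 3D about its own center
    (yaw about the vertical image axis foreshortens the eye the way a turned
    fish head does; roll rotates in-plane) and re-projected by a pinhole
    camera at distance ``focal_factor * w``.  The image center is a fixed
    point, so the eye stays in frame for any tilt.
    """
    from .geometry3d import build_homography

    c = (w - 1) / 2.0
    d = focal_factor * w
    R = rotation_about_axis([0, 0, 1], roll_deg) @ rotation_about_axis([0, 1, 0], yaw_deg)
    s = w / 4.0
    src = np.array([[-s, -s], [s, -s], [s, s], [-s, s]])
    pts3 = np.hstack([src, np.zeros((4, 1))]) @ R.T
    dst = d * pts3[:, :2] / (d + pts3[:, 2:3])
    h = build_homography(src + c, dst + c)
    return h


def _odd(k: int) -> int:
    return k if k % 2 == 1 else k + 1


def sample_pupil(w: int, rng: np.random.Generator) -> Circle:
    """Draw the pupil circle of the validation recipe.

    Radius uniform in [w/6 - w/20, w/6 + w/20] px, center uniform in
    [w/2 - w/6, w/2 + w/6] px per axis, resampled until the pupil lies fully
    inside the sclera disk (diameter 2w/3 at the image center).
    """
    center = (w - 1) / 2.0
    sclera_r = w / 3.0
    r_lo, r_hi = w / 6.0 - w / 20.0, w / 6.0 + w / 20.0
    c_lo, c_hi = w / 2.0 - w / 6.0, w / 2.0 + w / 6.0
    while True:
        pr = rng.uniform(r_lo, r_hi)
        px, py = rng.uniform(c_lo, c_hi, size=2)
        if math.hypot(px - center, py - center) + pr <= sclera_r:
            return Circle(px, py, 2.0 * pr)


def synthesize_eye_image(
    w: int,
    rng_seed: int | np.random.Generator | None = 0,
    *,
    background: float = 128.0,
    sclera_delta: float = 60.0,
    pupil_delta: float = -80.0,
    tilt_range_deg: float = 30.0,
    blur: bool = True,
    noise: bool = True,
) -> SynthEyeRecord:
    """Generate one synthesized fish-eye validation image with ground truth.

    Deterministic for a fixed seed (or pass a Generator to draw from an
    existing stream).  ``tilt_range_deg=0`` disables the perspective tilt and
    ``noise=False`` the white dots, giving the clean-limit fixture.
    """
    if w < 60:
        raise WTooSmallError(f"w={w} < 60: derived kernels/radii degenerate")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    seed = None if isinstance(rng_seed, np.random.Generator) else int(rng_seed)

    center = (w - 1) / 2.0
    sclera = Circle(center, center, 2.0 * w / 3.0)
    pupil = sample_pupil(w, rng)

    img = np.full((w, w), background, dtype=float)
    rr, cc = draw_disk((sclera.cy, sclera.cx), sclera.radius, shape=img.shape)
    img[rr, cc] = background + sclera_delta
    rr, cc = draw_disk((pupil.cy, pupil.cx), pupil.radius, shape=img.shape)
    img[rr, cc] = background + pupil_delta

    if tilt_range_deg > 0:
        yaw = rng.uniform(-tilt_range_deg, tilt_range_deg)
        roll = rng.uniform(-tilt_range_deg, tilt_range_deg)
        tilt = _tilt_homography(w, yaw, roll)
        img = warp_image(img, tilt, (w, w), cval=background)
    else:
        tilt = Homography(np.eye(3))

    kernel = _odd(int(round(w / 6.0)))
    if blur:
        # sigma from kernel size per the usual box-of-3-sigma convention
        sigma = 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8
        img = ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")

    n_noise = int(round(0.0005 * w * w)) if noise else 0
    if n_noise:
        flat = rng.choice(w * w, size=n_noise, replace=False)
        img.flat[flat] = 255.0

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SynthEyeRecord(image=img, w=w, true_sclera=sclera, true_pupil=pupil,
                          tilt_homography=tilt, noise_count=n_noise,
                          blur_kernel=kernel, background=background, seed=seed)


# ---------------------------------------------------------------------------
# linear blend skinning
# ---------------------------------------------------------------------------

@dataclass
class Skeleton:
    """Skeleton along the anteroposterior (x) axis: joints head-to-tail.

    ``joints`` is a (K, 3) array of rest-frame joint positions with strictly
    decreasing x (head first); bone i spans joints i..i+1.
    """

    joints: np.ndarray

    def __post_init__(self):
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.ndim != 2 or self.joints.shape[1] != 3 or len(self.joints) < 2:
            raise ValueError("joints must be (K>=2, 3)")

    @property
    def n_bones(self) -> int:
        return len(self.joints) - 1

    def vertex_weights(self, vertices: np.ndarray) -> np.ndarray:
        """(N, n_bones) normalized skinning weights from x-position.

        Each vertex is weighted over bones by a triangular kernel centered on
        the bone midpoint with bandwidth one bone length, which yields a
        smooth, partition-of-unity blend along the body.
        """
        x = np.asarray(vertices, dtype=float)[:, 0]
        mids = 0.5 * (self.joints[:-1, 0] + self.joints[1:, 0])
        spans = np.abs(self.joints[:-1, 0] - self.joints[1:, 0])
        w = np.maximum(0.0, 1.0 - np.abs(x[:, None] - mids[None, :]) / spans[None, :])
        # vertices beyond the end joints attach fully to the end bones
        w[x >= mids[0], 0] = np.maximum(w[x >= mids[0], 0], 1.0)
        w[x <= mids[-1], -1] = np.maximum(w[x <= mids[-1], -1], 1.0)
        return w / w.sum(axis=1, keepdims=True)


def lbs_deform(
    base_vertices: np.ndarray,
    skeleton: Skeleton,
    bone_yaws: np.ndarray,
    bone_rolls: np.ndarray | None = None,
    bone_pitches: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    bone_stretches: np.ndarray | None = None,
) -> np.ndarray:
    """Deform a rest mesh by weight-blended bone transforms (LBS).

    Bones rotate in yaw (body bending left/right) and slight roll, chained
    head to tail; pitch is forbidden.  ``bone_stretches`` scales bone lengths
    (stretching a segment spreads its vertices, reducing vertex density).
    """
    V = np.asarray(base_vertices, dtype=float)
    nb = skeleton.n_bones
    yaws = np.broadcast_to(np.asarray(bone_yaws, dtype=float), (nb,))
    rolls = (np.zeros(nb) if bone_rolls is None
             else np.broadcast_to(np.asarray(bone_rolls, dtype=float), (nb,)))
    if bone_pitches is not None and np.any(np.asarray(bone_pitches) != 0):
        raise PitchForbiddenError("skeleton bones may not pitch")
    stretch = (np.ones(nb) if bone_stretches is None
               else np.broadcast_to(np.asarray(bone_stretches, dtype=float), (nb,)))
    W = skeleton.vertex_weights(V) if weights is None else np.asarray(weights, dtype=float)
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("skinning weights must sum to 1 per vertex")

    # world transform of bone b: A_b(v) = p_b + Rcum_b @ (v - j_b) with the
    # chain anchored at the head joint (bone 0 starts undeformed)
    Rcum = np.eye(3)
    p = skeleton.joints[0].copy()
    transforms = []
    for b in range(nb):
        Rb = rotation_about_axis([0, 0, 1], yaws[b]) @ rotation_about_axis([1, 0, 0], rolls[b])
        Rcum = Rcum @ Rb
        j = skeleton.joints[b]
        transforms.append((p.copy(), Rcum.copy(), j, stretch[b]))
        # advance the anchor to the next joint's deformed position
        seg = skeleton.joints[b + 1] - j
        p = p + Rcum @ (stretch[b] * seg)

    out = np.zeros_like(V)
    for b, (pb, Rb, jb, sb) in enumerate(transforms):
        local = V - jb
        local = local * np.array([sb, 1.0, 1.0])  # stretch along the bone axis
        out += W[:, b:b + 1] * (pb + local @ Rb.T)
    return out


# ---------------------------------------------------------------------------
# fish mesh
# ---------------------------------------------------------------------------

def make_fish_mesh(
    body_length: float = 0.12,
    body_width: float = 0.025,
    body_height: float = 0.035,
    eye_azimuth_deg: float = 60.0,
    subdivisions: int = 2,
) -> dict:
    """Procedural rest-frame fish body: an ellipsoid with eye anchors.

    Returns a dict with ``vertices`` (N, 3), ``faces`` (M, 3), eye anchor
    vertex indices and rest-frame eye normals at ``+/-eye_azimuth_deg`` of
    azimuth off the anterior axis.  Local frame: x anterior, y left, z up;
    origin at the body centroid.
    """
    import trimesh

    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    V = sphere.vertices * np.array([body_length / 2, body_width / 2, body_height / 2])
    F = np.asarray(sphere.faces)

    az = np.deg2rad(eye_azimuth_deg)
    # eye sits on the head flank, forward of center and slightly dorsal
    x_eye = 0.33 * body_length
    y_surf = (body_width / 2) * np.sqrt(max(0.0, 1 - (x_eye / (body_length / 2)) ** 2))
    anchors = {}
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        target = np.array([x_eye, sgn * y_surf, 0.15 * body_height])
        anchors[side] = int(np.argmin(np.linalg.norm(V - target, axis=1)))
    normals = {
        "left": np.array([np.cos(az), np.sin(az), 0.0]),
        "right": np.array([np.cos(az), -np.sin(az), 0.0]),
    }
    return {
        "vertices": V,
        "faces": F,
        "eye_anchor_left": anchors["left"],
        "eye_anchor_right": anchors["right"],
        "eye_normal_left": normals["left"],
        "eye_normal_right": normals["right"],
        "body_length": body_length,
    }


# ---------------------------------------------------------------------------
# two-camera scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Conditions of a synthetic two-fish flow-tank recording.

    Defaults emulate the study setup: two goldfish (body length 0.12 m,
    average eye diameter 6.75 mm) holding station against a 1.4 BL/s flow in
    a 0.88 x 0.25 x 0.25 m arena recorded at 90 fps by a backlit bottom view
    and a perpendicular side view.  The leader swims ~0.3 m ahead and weaves
    laterally; eye behavior 'fixating' aims the follower's pupils at the
    leader's centroid.
    """

    n_fish: int = 2
    n_frames: int = 200
    fps: float = 90.0
    flow_speed_bls: float = 1.4
    body_length: float = 0.12
    body_width: float = 0.025
    body_height: float = 0.035
    eye_diameter_mm: float = 6.75
    eye_azimuth_deg: float = 60.0
    eye_behavior: str = "fixating"      # fixating | static | random
    follower_xyz: tuple = (0.25, 0.125, 0.125)
    leader_dx: float = 0.21             # leader ahead along the flow axis
    leader_dy: float = -0.065           # offset to the follower's right
    leader_sway_m: float = 0.04         # lateral weave amplitude
    leader_sway_period_s: float = 1.6
    leader_bob_m: float = 0.02          # vertical bobbing amplitude
    leader_bob_period_s: float = 2.1
    follower_yaw_deg: float = 8.0       # heading oscillation amplitude
    follower_yaw_period_s: float = 1.1
    roll_deg: float = 2.0               # body roll oscillation amplitude
    tail_beat_deg: float = 10.0
    tail_beat_hz: float = 2.5
    station_jitter_m: float = 0.008     # station-holding positional wobble
    max_pupil_excursion_deg: float = 85.0
    side_image_size: tuple = (2560, 1024)
    side_focal_px: float = 12000.0
    side_camera_distance: float = 1.0
    bottom_image_size: tuple = (640, 480)
    bottom_focal_px: float = 700.0
    n_bones: int = 5


@dataclass
class SynthScene:
    """Synthetic scene: per-frame poses, cameras, and ground-truth gaze.

    ``truth`` is a DataFrame with one row per (frame, fish, eye) holding the
    3D pupil point, gaze direction and normalized offset.  Frames are rendered
    lazily via :meth:`render_frame` to keep memory bounded.
    """

    config: SceneConfig
    seed: int
    poses: list          # poses[fish_id][frame] -> FishPose
    cameras: dict        # {'side': CameraModel, 'bottom': CameraModel}
    truth: "object"      # pandas.DataFrame
    mesh_faces: np.ndarray = field(repr=False, default=None)
    rest_vertices: np.ndarray = field(repr=False, default=None)

    def render_frame(self, frame_index: int, view: str = "side",
                     blur_sigma: float = 1.0) -> np.ndarray:
        cam = self.cameras[view]
        w, h = cam.image_size
        # bottom view is backlit (bright field, dark fish); side view is lit
        img = np.full((h, w), 235.0 if view == "bottom" else 30.0)
        order = []  # (depth, kind, payload) far-to-near painter's order
        for fid in range(self.config.n_fish):
            pose = self.poses[fid][frame_index]
            depth = ((pose.position @ cam.rotation.T) + cam.translation)[2]
            order.append((depth, fid, pose))
        for depth, fid, pose in sorted(order, key=lambda t: -t[0]):
            self._draw_fish(img, cam, pose, fid, frame_index, view)
        if blur_sigma > 0:
            img = ndimage.gaussian_filter(img, blur_sigma, mode="nearest")
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    def _draw_fish(self, img, cam, pose, fish_id, frame_index, view):
        try:
            uv = project_point(cam, pose.mesh_vertices)
        except Exception:
            return
        depths = (pose.mesh_vertices @ cam.rotation.T + cam.translation)[:, 2]
        faces = self.mesh_faces
        tri_depth = depths[faces].mean(axis=1)
        body_val = 0.0 if view == "bottom" else 100.0
        for ti in np.argsort(-tri_depth):
            tri = uv[faces[ti]]
            rr, cc = draw_polygon(tri[:, 1], tri[:, 0], shape=img.shape)
            img[rr, cc] = body_val
        if view != "side":
            return
        # eyes: sclera = projected silhouette of the eye sphere, pupil = dark
        # disk at the projected 3D pupil point, clipped to the sclera
        r_eye = pose.eye_radius_m
        for side in ("left", "right"):
            n = eye_outward_normal(pose, side)
            if np.dot(n, (eye_anchor_position(pose, side) - cam.center)) >= 0:
                continue  # eye on the far flank
            center3d = eye_anchor_position(pose, side) - r_eye * n
            c_uv = project_point(cam, center3d)
            z = (center3d @ cam.rotation.T + cam.translation)[2]
            r_px = cam.focal_length * r_eye / z
            rr, cc = draw_disk((c_uv[1], c_uv[0]), r_px, shape=img.shape)
            img[rr, cc] = 200.0
            row = self.truth[(self.truth.frame == frame_index)
                             & (self.truth.fish_id == fish_id)
                             & (self.truth.eye_side == side)]
            if not len(row):
                continue
            p3d = row.iloc[0][["pupil_x", "pupil_y", "pupil_z"]].to_numpy(dtype=float)
            p_uv = project_point(cam, p3d)
            # the pupil is a cap on the eye sphere: seen obliquely it
            # foreshortens to an ellipse (minor axis along the radial image
            # direction, scaled by the cosine of the viewing angle)
            n_p = (p3d - center3d) / r_eye
            v = center3d - cam.center
            v = v / np.linalg.norm(v)
            cos_psi = float(-np.dot(n_p, v))
            if cos_psi <= 0.05:
                continue  # pupil turned past the silhouette rim
            a_t = 0.45 * r_px
            a_r = a_t * cos_psi
            u = p_uv - c_uv
            un = np.linalg.norm(u)
            u = u / un if un > 1e-9 else np.array([1.0, 0.0])
            uperp = np.array([-u[1], u[0]])
            lo = np.maximum(np.floor(p_uv - a_t - 1).astype(int), 0)
            hi = np.minimum(np.ceil(p_uv + a_t + 2).astype(int),
                            [img.shape[1], img.shape[0]])
            if np.any(hi <= lo):
                continue
            yy2, xx2 = np.mgrid[lo[1]:hi[1], lo[0]:hi[0]]
            dx, dy = xx2 - p_uv[0], yy2 - p_uv[1]
            e = ((dx * u[0] + dy * u[1]) / a_r) ** 2 + \
                ((dx * uperp[0] + dy * uperp[1]) / a_t) ** 2
            img[lo[1]:hi[1], lo[0]:hi[0]][e <= 1.0] = 40.0


def _default_cameras(cfg: SceneConfig) -> dict:
    cx = cfg.follower_xyz[0] + 0.5 * cfg.leader_dx
    # side camera: placed along the follower's right-eye optical axis (the
    # -eye_azimuth direction) so that eye is viewed nearly face-on, the way
    # the recording view that tracks an eye should be oriented
    az = np.deg2rad(cfg.eye_azimuth_deg)
    out_dir = np.array([np.cos(az), -np.sin(az), 0.0])  # right-eye rest axis
    C_side = np.asarray(cfg.follower_xyz) + cfg.side_camera_distance * out_dir
    z_cam = -out_dir                                    # looks back at the fish
    x_cam = np.cross(np.array([0.0, 0.0, 1.0]), z_cam)
    x_cam = -x_cam / np.linalg.norm(x_cam)              # keep image y downward
    y_cam = np.cross(z_cam, x_cam)
    R_side = np.vstack([x_cam, y_cam, z_cam])
    side = CameraModel(
        focal_length=cfg.side_focal_px,
        principal_point=(cfg.side_image_size[0] / 2, cfg.side_image_size[1] / 2),
        rotation=R_side, translation=-R_side @ C_side,
        image_size=tuple(cfg.side_image_size),
    )
    # bottom camera: below the tank, looking up (+z); image x = world x
    R_bot = np.eye(3)
    C_bot = np.array([cx, 0.125, -0.8])
    bottom = CameraModel(
        focal_length=cfg.bottom_focal_px,
        principal_point=(cfg.bottom_image_size[0] / 2, cfg.bottom_image_size[1] / 2),
        rotation=R_bot, translation=-R_bot @ C_bot,
        image_size=tuple(cfg.bottom_image_size),
    )
    return {"side": side, "bottom": bottom}


def _fixate_pupil(center3d, r_eye, normal, target, max_excursion_deg):
    """3D pupil point on the eye sphere aiming the gaze at ``target``.

    The pupil is the sphere-surface point in the gaze direction; when the
    target lies beyond the admissible excursion from the optical axis the
    pupil clamps to the sclera rim (max excursion) in the target's plane.
    """
    d = target - center3d
    d = d / np.linalg.norm(d)
    cosang = float(np.clip(np.dot(d, normal), -1.0, 1.0))
    ang = np.degrees(np.arccos(cosang))
    if ang > max_excursion_deg:
        # rotate the normal toward the target by the max excursion
        axis = np.cross(normal, d)
        if np.linalg.norm(axis) < 1e-12:
            d = normal
        else:
            d = rotation_about_axis(axis, max_excursion_deg) @ normal
    return center3d + r_eye * d


def synthesize_scene(config: SceneConfig | None = None,
                     rng_seed: int = 0) -> SynthScene:
    """Build a deterministic synthetic scene per ``config``.

    Raises :class:`OutOfArenaError` if a trajectory leaves the arena.
    """
    import pandas as pd

    cfg = config or SceneConfig()
    rng = np.random.default_rng(rng_seed)
    mesh = make_fish_mesh(cfg.body_length, cfg.body_width, cfg.body_height,
                          cfg.eye_azimuth_deg)
    joints_x = np.linspace(cfg.body_length / 2, -cfg.body_length / 2, cfg.n_bones + 1)
    skel = Skeleton(np.column_stack([joints_x, np.zeros_like(joints_x),
                                     np.zeros_like(joints_x)]))

    t = np.arange(cfg.n_frames) / cfg.fps
    phase = rng.uniform(0, 2 * np.pi, size=(cfg.n_fish, 3))
    jitter = cfg.station_jitter_m * np.column_stack([
        np.sin(2 * np.pi * t / 2.3 + phase[0, 0]),
        np.zeros_like(t),
        np.sin(2 * np.pi * t / 1.9 + phase[0, 1]),
    ])

    poses: list[list[FishPose]] = [[] for _ in range(cfg.n_fish)]
    rows = []
    f0 = np.asarray(cfg.follower_xyz, dtype=float)
    for i in range(cfg.n_frames):
        # follower: station-holding, heading oscillates in yaw
        yaw_f = cfg.follower_yaw_deg * np.sin(2 * np.pi * t[i] / cfg.follower_yaw_period_s
                                              + phase[0, 2])
        centers = {0: f0 + jitter[i]}
        yaws = {0: yaw_f}
        # leader: ahead, weaving laterally; heading follows its velocity
        sway = cfg.leader_sway_m * np.sin(2 * np.pi * t[i] / cfg.leader_sway_period_s
                                          + phase[1 % cfg.n_fish, 0])
        dsway = (cfg.leader_sway_m * 2 * np.pi / cfg.leader_sway_period_s
                 * np.cos(2 * np.pi * t[i] / cfg.leader_sway_period_s
                          + phase[1 % cfg.n_fish, 0]))
        speed = cfg.flow_speed_bls * cfg.body_length
        bob = cfg.leader_bob_m * np.sin(2 * np.pi * t[i] / cfg.leader_bob_period_s
                                        + phase[1 % cfg.n_fish, 2])
        for fid in range(1, cfg.n_fish):
            centers[fid] = f0 + np.array([cfg.leader_dx * fid,
                                          cfg.leader_dy + sway, bob])
            yaws[fid] = np.degrees(np.arctan2(dsway, speed))

        for fid in range(cfg.n_fish):
            pos = centers[fid]
            if np.any(pos < 0) or np.any(pos > ARENA_SIZE):
                raise OutOfArenaError(f"fish {fid} at {pos} leaves the arena")
            yaw = yaws[fid]
            heading = np.array([np.cos(np.deg2rad(yaw)), np.sin(np.deg2rad(yaw)), 0.0])
            roll = cfg.roll_deg * np.sin(2 * np.pi * t[i] / 1.4 + phase[fid, 1])
            tail = cfg.tail_beat_deg * np.sin(2 * np.pi * cfg.tail_beat_hz * t[i]
                                              + phase[fid, 2])
            bone_yaws = tail * np.linspace(0, 1, cfg.n_bones) ** 2
            V = lbs_deform(mesh["vertices"], skel, bone_yaws,
                           np.zeros(cfg.n_bones))
            R = rotation_about_axis([0, 0, 1], yaw) @ rotation_about_axis([1, 0, 0], 0)
            Rroll = rotation_about_axis(heading, roll)
            V = (Rroll @ R @ V.T).T + pos
            pose = FishPose(
                frame_index=i, position=pos, heading=heading, roll=roll,
                bone_yaws=bone_yaws, bone_rolls=np.zeros(cfg.n_bones),
                mesh_vertices=V, mesh_faces=mesh["faces"],
                eye_anchor_left=mesh["eye_anchor_left"],
                eye_anchor_right=mesh["eye_anchor_right"],
                eye_diameter=cfg.eye_diameter_mm,
                eye_normal_left=mesh["eye_normal_left"],
                eye_normal_right=mesh["eye_normal_right"],
            )
            poses[fid].append(pose)

    # ground-truth gaze for the follower (fish 0) toward the leader (fish 1)
    for i in range(cfg.n_frames):
        follower = poses[0][i]
        target = poses[1 % cfg.n_fish][i].position
        for side in ("left", "right"):
            n = eye_outward_normal(follower, side)
            anchor = eye_anchor_position(follower, side)
            c3d = anchor - follower.eye_radius_m * n
            if cfg.eye_behavior == "static":
                p3d = anchor
            elif cfg.eye_behavior == "random":
                p3d = _random_pupil(rng, c3d, follower.eye_radius_m, n,
                                    cfg.max_pupil_excursion_deg)
            else:
                p3d = _fixate_pupil(c3d, follower.eye_radius_m, n, target,
                                    cfg.max_pupil_excursion_deg)
            g = p3d - c3d
            g = g / np.linalg.norm(g)
            off = _normalized_offset_3d(p3d, c3d, n, follower)
            rows.append(dict(frame=i, fish_id=0, eye_side=side,
                             pupil_x=p3d[0], pupil_y=p3d[1], pupil_z=p3d[2],
                             eye_center_x=c3d[0], eye_center_y=c3d[1],
                             eye_center_z=c3d[2],
                             gaze_x=g[0], gaze_y=g[1], gaze_z=g[2],
                             offset_ap=off))
    truth = pd.DataFrame(rows)
    scene = SynthScene(config=cfg, seed=int(rng_seed), poses=poses,
                       cameras=_default_cameras(cfg), truth=truth,
                       mesh_faces=mesh["faces"],
                       rest_vertices=mesh["vertices"])
    return scene


def _random_pupil(rng, center3d, r_eye, normal, max_excursion_deg):
    """Uniform pupil placement within the admissible sclera interior."""
    while True:
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v)
        ang = np.degrees(np.arccos(np.clip(np.dot(v, normal), -1, 1)))
        if ang <= max_excursion_deg:
            return center3d + r_eye * v


def _normalized_offset_3d(p3d, c3d, normal, pose) -> float:
    """Anteroposterior normalized pupil offset implied by the 3D pupil point.

    The pupil's displacement from the optical axis, projected on the fish's
    anterior direction within the eye's tangent plane, divided by the eye
    diameter (matching the 2D definition offset = displacement / diameter).
    """
    d = (p3d - c3d) / np.linalg.norm(p3d - c3d)
    from .geometry3d import fish_basis
    f, _, _ = fish_basis(pose)
    a1 = f - np.dot(f, normal) * normal
    a1 = a1 / np.linalg.norm(a1)
    return float(np.dot(d, a1) / 2.0)  # sin(component angle)/2 at unit sphere
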