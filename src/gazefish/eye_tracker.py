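"""Sclera/pupil detection on rectified eye crops, 3D back-projection, gaze.

Detection is classical: the sclera is the large light disk (Otsu threshold,
largest bright connected component, holes filled so the dark pupil does not
bias the center), the pupil is the small dark disk inside it (darkest-decile
seed, then a refined half-contrast threshold).  Centers are area centroids
and diameters area-equivalent circle diameters, which are robust to the
heavy Gaussian blur and sparse white-dot noise of backlit fish imagery —
a boundary-based enclosing circle would be dragged by single noise pixels.

Eye geometry: the eyeball is a sphere of the fish's eye diameter centered
one radius beneath the sclera anchor on the mesh.  The gaze ray starts at
the retina center (the sphere center) and points through the 3D pupil.
A pupil displaced from the sclera center by a normalized offset o (pupil
displacement / sclera diameter) sits at spherical angle asin(2|o|) from the
eye's optical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import find_contours, label

from .errors import (
    BackprojectionMissError,
    DegenerateGazeError,
    PupilNotFoundError,
    ScleraNotFoundError,
)
from .geometry3d import (
    CameraModel,
    FishPose,
    Homography,
    eye_anchor_position,
    eye_outward_normal,
    fish_basis,
)
from .synth_data import Circle

__all__ = [
    "EyeState",
    "GazeRay",
    "detect_sclera",
    "detect_pupil",
    "back_project_eye",
    "gaze_from_eye",
    "normalize_eye_movement",
    "classify_pupil_position",
    "gaze_direction_from_circles",
    "AVERAGE_EYE_DIAMETER_MM",
]

#: population-average goldfish eye diameter used to express pixel errors in mm
AVERAGE_EYE_DIAMETER_MM = 6.75


@dataclass
class EyeState:
    """Detected eye on one frame: 2D circles, 3D back-projections, offsets."""

    frame_index: int
    eye_side: str
    sclera: Circle | None = None
    pupil: Circle | None = None
    sclera_center_3d: np.ndarray | None = None
    pupil_center_3d: np.ndarray | None = None
    normalized_offset: np.ndarray | None = None   # (ap, dv), dimensionless
    view_angle: float | None = None               # deg off the optical axis
    status: str = "ok"

    def offset_from_circles(self) -> np.ndarray:
        """Normalized pupil offset: (pupil - sclera center) / sclera diameter."""
        o = (self.pupil.center - self.sclera.center) / self.sclera.diameter
        return o


@dataclass(frozen=True)
class GazeRay:
    """Viewing ray: origin at the retina center, unit direction to the pupil."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateGazeError("zero-length gaze direction")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _component_circle(mask: np.ndarray) -> Circle:
    """Area centroid + area-equivalent diameter of a boolean component."""
    filled = ndimage.binary_fill_holes(mask)
    ys, xs = np.nonzero(filled)
    area = len(xs)
    return Circle(float(xs.mean()), float(ys.mean()),
                  2.0 * np.sqrt(area / np.pi))


def _fit_circle(points: np.ndarray, n_trim: int = 3) -> Circle:
    """Trimmed algebraic (Kasa) least-squares circle fit to (x, y) points.

    Points whose radial residual exceeds 2.5 robust sigmas are dropped and
    the fit repeated, which rejects boundary stretches distorted by noise
    dots or by the pupil notching the sclera rim.
    """
    pts = np.asarray(points, dtype=float)
    for _ in range(n_trim):
        x, y = pts[:, 0], pts[:, 1]
        A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        b = x * x + y * y
        (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
        r = np.sqrt(max(c + cx * cx + cy * cy, 1e-12))
        res = np.abs(np.hypot(x - cx, y - cy) - r)
        sigma = 1.4826 * np.median(res) + 1e-9
        keep = res < 2.5 * sigma
        if keep.all() or keep.sum() < 6:
            break
        pts = pts[keep]
    return Circle(float(cx), float(cy), float(2 * r))


def _subpixel_circle(img: np.ndarray, level: float, near: Circle,
                     min_len: int = 8,
                     exclude: Circle | None = None,
                     exclude_margin: float = 0.0,
                     rim: Circle | None = None,
                     rim_margin: float = 0.0) -> Circle | None:
    """Fit a circle to the half-level iso-contour of a blurred disk edge.

    For a Gaussian-blurred step edge the half-contrast crossing coincides
    with the true edge even when the blur is anisotropic (as it is after
    rectifying a tilted image), so the iso-contour at the midpoint between
    the two plateau intensities localizes the disk rim to sub-pixel accuracy.
    Contour points within ``exclude_margin`` px of the ``exclude`` circle's
    rim are dropped before fitting — where two blurred disks meet (pupil
    against sclera rim) the iso-contour detours and would bias the fit.
    Returns None when no usable contour surrounds ``near``.
    """
    contours = [c for c in find_contours(np.asarray(img, dtype=float), level)
                if len(c) >= min_len]
    if not contours:
        return None
    # prefer the longest contour whose centroid is nearest the expected circle
    def score(c):
        cy, cx = c.mean(axis=0)
        return np.hypot(cx - near.cx, cy - near.cy) - 0.01 * len(c)
    best = min(contours, key=score)
    if np.hypot(*(best.mean(axis=0)[::-1] - near.center)) > near.radius:
        return None
    pts = best[:, ::-1]  # (row, col) -> (x, y)
    if exclude is not None:
        d = np.hypot(pts[:, 0] - exclude.cx, pts[:, 1] - exclude.cy)
        keep = d > exclude.radius + exclude_margin
        # never discard most of the contour: a circle fit needs a long arc
        if keep.sum() >= max(min_len, 0.4 * len(pts)):
            pts = pts[keep]
    if rim is not None:
        d = np.hypot(pts[:, 0] - rim.cx, pts[:, 1] - rim.cy)
        keep = d < rim.radius - rim_margin
        if keep.sum() >= max(min_len, 0.4 * len(pts)):
            pts = pts[keep]
    return _fit_circle(pts)


def detect_sclera(
    rectified_crop: np.ndarray,
    min_area: int = 50,
    mask: np.ndarray | None = None,
    exclude_pupil: Circle | None = None,
) -> Circle:
    """Detect the eye sclera (large light disk) on a rectified crop.

    Thresholds at Otsu's level, keeps the largest bright connected component
    (area >= ``min_area`` px^2), fills its holes (the pupil) and returns the
    centroid / area-equivalent circle.  An externally supplied boolean
    ``mask`` (nonzero = sclera) bypasses thresholding entirely.

    Raises :class:`ScleraNotFoundError` when no component qualifies.
    """
    img = np.asarray(rectified_crop, dtype=float)
    if mask is not None:
        candidates = [np.asarray(mask) > 0]
    else:
        if np.ptp(img) < 1e-9:
            raise ScleraNotFoundError("uniform crop: no bright disk")
        # the crop has up to three intensity modes (pupil, background,
        # sclera); the sclera is the upper one.  Multi-Otsu isolates it when
        # a large pupil skews the histogram, plain Otsu when there are only
        # two modes — try both and keep the first plausible disk.
        thrs = []
        try:
            thrs.append(threshold_multiotsu(img, classes=3)[-1])
        except ValueError:  # too few distinct gray levels
            pass
        thrs.append(threshold_otsu(img))
        # +0.5 gray level: Otsu variants can land infinitesimally below a
        # plateau value, which would flip the whole plateau to "bright"
        candidates = [img > t + 0.5 for t in thrs]

    best_mask = None
    for bright in candidates:
        lab, n = label(bright, return_num=True, connectivity=2)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        k = int(np.argmax(sizes)) + 1
        if sizes[k - 1] < min_area:
            continue
        if mask is None and sizes[k - 1] > 0.6 * img.size:
            continue  # implausible: the "sclera" swallowed the whole crop
        best_mask = lab == k
        break
    if best_mask is None:
        raise ScleraNotFoundError("no plausible bright disk component")
    init = _component_circle(best_mask)

    if exclude_pupil is None and mask is None:
        # crude self-exclusion: locate the dark core inside the disk so the
        # rim fit below is not notched by a rim-hugging pupil
        try:
            _, crude = _dark_core(img, init)
            # the darkest-decile core underestimates a blurred pupil's
            # extent; inflate the exclusion zone to cover the full disk
            exclude_pupil = Circle(crude.cx, crude.cy, 1.6 * crude.diameter)
        except PupilNotFoundError:
            exclude_pupil = None

    # sub-pixel refinement: fit the half-contrast iso-contour of the rim
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    rr2 = (xx - init.cx) ** 2 + (yy - init.cy) ** 2
    inner_sel = rr2 <= (0.6 * init.radius) ** 2
    if exclude_pupil is not None:
        # keep the pupil out of the sclera-brightness estimate
        pd2 = (xx - exclude_pupil.cx) ** 2 + (yy - exclude_pupil.cy) ** 2
        inner_sel &= pd2 > exclude_pupil.radius ** 2
    inner = img[inner_sel]
    outer = img[rr2 >= (1.3 * init.radius) ** 2]
    if inner.size and outer.size:
        sclera_level = float(np.quantile(inner, 0.8))  # upper mode: skip pupil
        bg_level = float(np.median(outer))
        if sclera_level - bg_level > 1.0:
            margin = 0.18 * init.radius  # ~2 blur sigmas at the recipe scale
            refined = _subpixel_circle(
                img, 0.5 * (sclera_level + bg_level), init,
                exclude=exclude_pupil, exclude_margin=margin)
            # sanity: a wrong-contour fit lands far from the init's scale
            if refined is not None and 0.45 < refined.diameter / init.diameter < 2.2:
                if mask is None:
                    # second iteration: a better circle gives a better pupil
                    # exclusion, which un-notches the rim fit
                    try:
                        _, crude2 = _dark_core(img, refined)
                        excl2 = Circle(crude2.cx, crude2.cy, 1.6 * crude2.diameter)
                        again = _subpixel_circle(
                            img, 0.5 * (sclera_level + bg_level), refined,
                            exclude=excl2, exclude_margin=0.18 * refined.radius)
                        if again is not None and \
                                0.45 < again.diameter / refined.diameter < 2.2:
                            return again
                    except PupilNotFoundError:
                        pass
                return refined
    return init


def _sclera_mask(shape, sclera: Circle) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (xx - sclera.cx) ** 2 + (yy - sclera.cy) ** 2 <= sclera.radius ** 2


def _dark_core(img: np.ndarray, sclera: Circle,
               seed_quantile: float = 0.10) -> tuple:
    """Seed blob for the pupil: darkest-decile component inside the sclera.

    Selection tie-breaks: largest area, then lowest mean intensity, then
    nearest the sclera center.  A blob confined entirely to the outer rim
    band (all pixels beyond 0.8 sclera radii) is boundary bleed, not a
    pupil.  Returns (mask, circle); raises :class:`PupilNotFoundError`.
    """
    inside = _sclera_mask(img.shape, sclera)
    vals = img[inside]
    if vals.size == 0:
        raise PupilNotFoundError("empty sclera interior")
    thr = np.quantile(vals, seed_quantile)
    dark = (img <= thr) & inside  # inclusive: plateaus quantize to one level
    lab, n = label(dark, return_num=True, connectivity=2)
    if n == 0:
        raise PupilNotFoundError("no dark blob inside the sclera")
    stats = []
    for k in range(1, n + 1):
        m = lab == k
        ys, xs = np.nonzero(m)
        stats.append((m.sum(), img[m].mean(),
                      np.hypot(xs.mean() - sclera.cx, ys.mean() - sclera.cy), k))
    stats.sort(key=lambda s: (-s[0], s[1], s[2]))
    core = lab == stats[0][3]
    ys, xs = np.nonzero(core)
    if np.hypot(xs - sclera.cx, ys - sclera.cy).min() > 0.8 * sclera.radius:
        raise PupilNotFoundError("dark pixels only at the sclera rim")
    return core, _component_circle(core)


def detect_pupil(
    rectified_crop: np.ndarray,
    sclera: Circle,
    seed_quantile: float = 0.10,
) -> Circle:
    """Detect the pupil (small dark disk) inside the sclera circle.

    Two-stage threshold: the darkest ``seed_quantile`` of intensities inside
    the sclera seeds the blob (largest area; ties by lowest mean intensity,
    then by distance to the sclera center); the blob is then re-segmented at
    the half-contrast level between its core and the sclera brightness, which
    recovers the blurred pupil boundary with sub-pixel-stable centroids.

    Raises :class:`PupilNotFoundError` when no dark blob lies inside.
    """
    img = np.asarray(rectified_crop, dtype=float)
    inside = _sclera_mask(img.shape, sclera)
    core, _ = _dark_core(img, sclera, seed_quantile)
    vals = img[inside]

    core_level = img[core].mean()
    sclera_level = np.quantile(vals, 0.75)
    if sclera_level - core_level < 1e-9:
        raise PupilNotFoundError("no contrast between blob and sclera")
    half = 0.5 * (core_level + sclera_level)
    refined = (img < half) & inside
    lab2 = label(refined, connectivity=2)
    cy, cx = ndimage.center_of_mass(core)
    k2 = lab2[int(round(cy)), int(round(cx))]
    blob = (lab2 == k2) if k2 > 0 else core
    circ = _component_circle(blob)

    sub = _subpixel_circle(img, half, circ,
                           rim=sclera, rim_margin=0.18 * sclera.radius)
    if sub is not None and abs(sub.diameter - circ.diameter) < 0.75 * sclera.diameter:
        circ = sub
    if circ.diameter >= sclera.diameter:
        circ = Circle(circ.cx, circ.cy, 0.99 * sclera.diameter)
    return circ


# ---------------------------------------------------------------------------
# gaze geometry
# ---------------------------------------------------------------------------

def gaze_direction_from_circles(sclera: Circle, pupil: Circle) -> np.ndarray:
    """Unit gaze direction implied by 2D circles in a fronto-parallel crop.

    Under orthographic eye-sphere geometry a pupil at normalized offset o
    (displacement / sclera diameter, |o| <= 0.5) lies at spherical angle
    asin(2|o|) off the viewing axis, so the direction in crop coordinates
    (x, y, z-toward-viewer) is ``(2 ox, 2 oy, sqrt(1 - 4|o|^2))``.
    """
    o = (pupil.center - sclera.center) / sclera.diameter
    s = 2.0 * o
    z2 = 1.0 - float(s @ s)
    if z2 < 0:  # grazing: clamp onto the rim
        s = s / np.linalg.norm(s)
        z2 = 0.0
    return np.array([s[0], s[1], np.sqrt(z2)])


def _ray_sphere(origin, direction, center, radius):
    oc = origin - center
    b = float(np.dot(direction, oc))
    c = float(np.dot(oc, oc)) - radius**2
    disc = b * b - c
    if disc < 0:
        raise BackprojectionMissError("ray misses the eye sphere")
    t = -b - np.sqrt(disc)
    if t < 0:
        t = -b + np.sqrt(disc)
    if t < 0:
        raise BackprojectionMissError("eye sphere behind the camera")
    return origin + t * direction


def back_project_eye(
    state: EyeState,
    h: Homography,
    pose: FishPose,
    camera: CameraModel,
) -> EyeState:
    """Lift detected 2D circles back to 3D points on the eye sphere.

    Crop pixels are mapped through ``h``:sup:`-1` to the original image and
    ray-cast from the camera onto the eye sphere (centered one eye radius
    beneath the sclera anchor, radius = eye radius); the nearest intersection
    is taken.  Raises :class:`BackprojectionMissError` if a ray misses.
    """
    n = eye_outward_normal(pose, state.eye_side)
    anchor = eye_anchor_position(pose, state.eye_side)
    r = pose.eye_radius_m
    center = anchor - r * n
    hinv = h.inverse
    out = {}
    for name, circ in (("sclera", state.sclera), ("pupil", state.pupil)):
        uv = hinv.apply(circ.center)
        ray = camera.pixel_ray(uv)
        out[name] = _ray_sphere(camera.center, ray, center, r)
    return replace(state, sclera_center_3d=out["sclera"],
                   pupil_center_3d=out["pupil"])


def gaze_from_eye(state: EyeState, pose: FishPose) -> GazeRay:
    """Gaze ray: retina center (one eye radius beneath the anchor) -> pupil."""
    n = eye_outward_normal(pose, state.eye_side)
    anchor = eye_anchor_position(pose, state.eye_side)
    origin = anchor - pose.eye_radius_m * n
    if state.pupil_center_3d is None:
        raise DegenerateGazeError("pupil_center_3d not set")
    return GazeRay(origin=origin, direction=state.pupil_center_3d - origin)


# ---------------------------------------------------------------------------
# normalized eye movement
# ---------------------------------------------------------------------------

def normalize_eye_movement(state: EyeState) -> float:
    """Normalized eye-movement scalar from the pupil's anteroposterior offset.

    The anteroposterior component of (pupil - sclera center) / sclera
    diameter, signed so that a positive value means the gaze swings toward
    the fish's left: anterior pupil displacement on the LEFT eye is positive,
    on the RIGHT eye negative.  |value| <= 0.5 by construction.

    Assumes the crop orientation produced by :func:`~gazefish.geometry3d.
    rectify_eye_crop` (+x anterior).
    """
    if state.normalized_offset is not None:
        ap = float(state.normalized_offset[0])
    else:
        ap = float(state.offset_from_circles()[0])
    return ap if state.eye_side == "left" else -ap


def classify_pupil_position(state: EyeState, edge_threshold: float = 0.20) -> str:
    """Split frames into 'center' and 'edge' pupil positions.

    'edge' iff the normalized offset magnitude exceeds ``edge_threshold``
    (default 0.20): pupils near the sclera rim are harder to segment because
    the blur mixes them with the surround.
    """
    o = (state.normalized_offset if state.normalized_offset is not None
         else state.offset_from_circles())
    return "edge" if float(np.linalg.norm(o)) > edge_threshold else "center"


def track_eye_in_crop(crop: np.ndarray, frame_index: int, eye_side: str,
                      min_sclera_area: int = 50,
                      sclera_mask: np.ndarray | None = None) -> EyeState:
    """Run sclera + pupil detection on a rectified crop and fill an EyeState.

    Detection runs in two rounds: the first pass localizes both disks, the
    second refits each disk's rim contour with the other disk's blur zone
    excluded, removing the mutual bias where pupil and sclera boundaries meet.
    """
    sclera0 = detect_sclera(crop, min_area=min_sclera_area, mask=sclera_mask)
    pupil0 = detect_pupil(crop, sclera0)
    sclera = detect_sclera(crop, min_area=min_sclera_area, mask=sclera_mask,
                           exclude_pupil=pupil0)
    pupil = detect_pupil(crop, sclera)
    state = EyeState(frame_index=frame_index, eye_side=eye_side,
                     sclera=sclera, pupil=pupil)
    off = state.offset_from_circles()
    mag = float(np.linalg.norm(off))
    if mag > 0.5:  # fit noise can push a rim pupil past the geometric bound
        off = off * (0.5 / mag)
    state.normalized_offset = off
    state.view_angle = float(np.degrees(np.arcsin(
        np.clip(2.0 * np.linalg.norm(state.normalized_offset), 0.0, 1.0))))
    return state
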