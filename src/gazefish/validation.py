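"""Validation harnesses: synthesized-eye benchmark and end-to-end scene runs.

The synthesized-eye benchmark mirrors the study's validation protocol: draw
seeded ground-truth eye images, rectify each with the (known) inverse of its
perspective tilt — standing in for the pose-derived homography — run the
detector, and compare against the generated truth.  Pixel errors are
expressed in millimeters by scaling the detected sclera diameter to the
population-average eye diameter of 6.75 mm; gaze errors are the angle
between detected and true gaze directions under the orthographic eye-sphere
model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import GazefishError
from .eye_tracker import (
    AVERAGE_EYE_DIAMETER_MM,
    EyeState,
    back_project_eye,
    classify_pupil_position,
    gaze_direction_from_circles,
    gaze_from_eye,
    normalize_eye_movement,
    track_eye_in_crop,
)
from .geometry3d import warp_image, rectify_eye_crop
from .synth_data import SynthScene, synthesize_eye_image

__all__ = ["run_eye_validation", "summarize_validation", "track_scene"]


def _angle_between(a: np.ndarray, b: np.ndarray) -> float:
    c = float(np.clip(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1))
    return float(np.degrees(np.arccos(c)))


def run_eye_validation(
    n: int = 500,
    w: int = 120,
    seed: int = 0,
    *,
    tilt_range_deg: float = 30.0,
    noise: bool = True,
    blur: bool = True,
    edge_threshold: float = 0.20,
) -> pd.DataFrame:
    """Generate ``n`` seeded eye images, track them, return per-image errors.

    Columns include pixel and mm position errors for pupil and sclera, the
    signed and absolute view-angle errors (degrees), the edge/center class of
    the true pupil position, and a ``status`` ('ok' or the failure kind).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rec = synthesize_eye_image(w, rng, tilt_range_deg=tilt_range_deg,
                                   noise=noise, blur=blur)
        # rectify with the known tilt inverse (the pose-derived homography
        # plays this role on real imagery)
        border = np.concatenate([rec.image[0], rec.image[-1],
                                 rec.image[:, 0], rec.image[:, -1]])
        rectified = warp_image(rec.image, rec.tilt_homography.inverse, (w, w),
                               cval=float(np.median(border)))
        row = dict(image=i, w=w)
        try:
            state = track_eye_in_crop(rectified, i, "left")
        except GazefishError as exc:
            row.update(status=type(exc).__name__)
            rows.append(row)
            continue

        mm_per_px = AVERAGE_EYE_DIAMETER_MM / state.sclera.diameter
        true_dir = gaze_direction_from_circles(rec.true_sclera, rec.true_pupil)
        det_dir = gaze_direction_from_circles(state.sclera, state.pupil)
        true_phi = np.degrees(np.arcsin(min(1.0, 2 * np.linalg.norm(rec.true_offset))))
        row.update(
            status="ok",
            sclera_err_px=float(np.linalg.norm(state.sclera.center
                                               - rec.true_sclera.center)),
            pupil_err_px=float(np.linalg.norm(state.pupil.center
                                              - rec.true_pupil.center)),
            sclera_diam_px=state.sclera.diameter,
            view_angle_err_deg=_angle_between(det_dir, true_dir),
            view_angle_signed_deg=float(state.view_angle - true_phi),
            true_offset_norm=float(np.linalg.norm(rec.true_offset)),
            pupil_class=classify_pupil_position(state, edge_threshold),
        )
        row["sclera_err_mm"] = row["sclera_err_px"] * mm_per_px
        row["pupil_err_mm"] = row["pupil_err_px"] * mm_per_px
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_validation(df: pd.DataFrame) -> dict:
    """Mean/sd/max per error metric plus failure count, as a plain dict."""
    ok = df[df.status == "ok"]
    out = {"n": int(len(df)), "n_failed": int((df.status != "ok").sum())}
    for col in ("view_angle_err_deg", "view_angle_signed_deg",
                "pupil_err_mm", "sclera_err_mm", "pupil_err_px", "sclera_err_px"):
        out[col] = {
            "mean": float(ok[col].mean()),
            "sd": float(ok[col].std()),
            "max_abs": float(ok[col].abs().max()),
        }
    return out


def track_scene(
    scene: SynthScene,
    fish_id: int = 0,
    eye_side: str = "right",
    crop_size: int = 160,
    view: str = "side",
) -> pd.DataFrame:
    """Run the full image pipeline on a synthetic scene and score it.

    For every frame: render the side view, rectify the eye region from the
    fish's pose, detect sclera and pupil, back-project through the homography
    onto the eye sphere, form the gaze ray, and compare with the generator's
    ground truth.  Returns one row per frame with the recovered gaze, the
    angular gaze error, and the normalized eye-movement scalar.
    """
    cam = scene.cameras[view]
    rows = []
    truth = scene.truth
    for i in range(scene.config.n_frames):
        pose = scene.poses[fish_id][i]
        row = dict(frame=i, fish_id=fish_id, eye_side=eye_side)
        t = truth[(truth.frame == i) & (truth.fish_id == fish_id)
                  & (truth.eye_side == eye_side)]
        try:
            frame = scene.render_frame(i, view=view)
            crop, h = rectify_eye_crop(frame, pose, eye_side, cam,
                                       crop_size=crop_size)
            state = track_eye_in_crop(crop, i, eye_side)
            state = back_project_eye(state, h, pose, cam)
            gaze = gaze_from_eye(state, pose)
        except GazefishError as exc:
            row.update(status=type(exc).__name__)
            rows.append(row)
            continue
        row.update(
            status="ok",
            gaze_x=gaze.direction[0], gaze_y=gaze.direction[1],
            gaze_z=gaze.direction[2],
            eye_movement=normalize_eye_movement(state),
            offset_ap=float(state.normalized_offset[0]),
            offset_dv=float(state.normalized_offset[1]),
            sclera_d_px=state.sclera.diameter,
        )
        if len(t):
            g_true = t.iloc[0][["gaze_x", "gaze_y", "gaze_z"]].to_numpy(dtype=float)
            row["gaze_err_deg"] = _angle_between(gaze.direction, g_true)
        rows.append(row)
    return pd.DataFrame(rows)
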