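"""Pipeline orchestration: scene serialization, stage chaining, artifacts.

Two standard runs are supported: ``validate`` (the synthesized-eye benchmark
with an error-summary JSON) and ``scene_e2e`` (synthesize a scene, track the
eye from rendered frames, reconstruct retinal positions under the tracked /
static / random conditions, and compute the behavioral statistics).
Per-frame failures are logged and skipped, never imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .behavior_stats import (
    bootstrap_std,
    correlate_eye_angle,
    filter_leader_follower,
    position_angle,
)
from .eye_tracker import GazeRay, gaze_from_eye
from .geometry3d import FishPose, eye_anchor_position, eye_outward_normal, fish_basis
from .io import RunConfig, config_hash, read_camera, write_camera, write_mesh, \
    write_track_csv
from .retina_view import place_retina_camera, render_neighbor
from .synth_data import SceneConfig, SynthScene, synthesize_scene
from .validation import run_eye_validation, summarize_validation, track_scene

log = logging.getLogger("gazefish")

__all__ = ["save_scene", "load_scene", "run_pipeline", "pair_frames_from_scene",
           "retinal_track", "retinal_condition_stats"]


def save_scene(scene: SynthScene, out_dir: str | Path,
               frames: str = "side") -> Path:
    """Write a scene to disk: poses CSV, truth CSV, cameras YAML, mesh, frames.

    ``frames`` is 'none', 'side' or 'both'; rendered frames go to
    ``frames_<view>/frame_%04d.png``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for fid, seq in enumerate(scene.poses):
        for p in seq:
            rows.append(dict(
                frame=p.frame_index, fish_id=fid,
                px=p.position[0], py=p.position[1], pz=p.position[2],
                heading_x=p.heading[0], heading_y=p.heading[1],
                heading_z=p.heading[2], roll_deg=p.roll,
                bone_yaws=";".join(f"{v:.6g}" for v in p.bone_yaws),
            ))
    write_track_csv(out / "poses.csv", pd.DataFrame(rows), seed=scene.seed)
    write_track_csv(out / "truth.csv", scene.truth, seed=scene.seed)
    for view, cam in scene.cameras.items():
        write_camera(out / f"camera_{view}.yaml", cam)
    p0 = scene.poses[0][0]
    write_mesh(out / "body_mesh.obj", scene.rest_vertices, scene.mesh_faces)
    sidecar = {
        "eye_anchor_left": int(p0.eye_anchor_left),
        "eye_anchor_right": int(p0.eye_anchor_right),
        "eye_diameter_mm": float(p0.eye_diameter),
        "eye_normal_left": [float(v) for v in p0.eye_normal_left],
        "eye_normal_right": [float(v) for v in p0.eye_normal_right],
        "n_frames": scene.config.n_frames,
        "body_length_m": float(scene.config.body_length),
        "n_bones": int(scene.config.n_bones),
        "seed": scene.seed,
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=2))
    views = {"none": [], "side": ["side"], "both": ["side", "bottom"]}[frames]
    for view in views:
        fdir = out / f"frames_{view}"
        fdir.mkdir(exist_ok=True)
        for i in range(scene.config.n_frames):
            iio.imwrite(fdir / f"frame_{i:04d}.png", scene.render_frame(i, view))
    return out


@dataclass
class LoadedScene:
    """A scene reloaded from disk; frames come from the saved PNGs.

    Quacks like :class:`~gazefish.synth_data.SynthScene` for the tracking
    code (``poses``, ``cameras``, ``truth``, ``config``, ``render_frame``).
    """

    config: SceneConfig
    seed: int
    poses: list
    cameras: dict
    truth: pd.DataFrame
    frame_dir: Path

    def render_frame(self, frame_index: int, view: str = "side") -> np.ndarray:
        path = self.frame_dir.parent / f"frames_{view}" / f"frame_{frame_index:04d}.png"
        return iio.imread(path)


def load_scene(scene_dir: str | Path) -> LoadedScene:
    """Reload a scene written by :func:`save_scene`.

    Per-frame meshes are rebuilt from the stored rest mesh and pose
    parameters through the same skinning model the generator used.
    """
    from .io import read_mesh, read_track_csv
    from .synth_data import Skeleton, lbs_deform
    from .geometry3d import rotation_about_axis

    d = Path(scene_dir)
    sidecar = json.loads((d / "scene.json").read_text())
    rest, F = read_mesh(d / "body_mesh.obj")
    pose_df = read_track_csv(d / "poses.csv")
    truth = read_track_csv(d / "truth.csv")
    cameras = {p.stem.split("_", 1)[1]: read_camera(p)
               for p in sorted(d.glob("camera_*.yaml"))}
    cfg = SceneConfig(n_frames=int(sidecar["n_frames"]),
                      body_length=float(sidecar.get("body_length_m", 0.12)),
                      n_bones=int(sidecar.get("n_bones", 5)),
                      eye_diameter_mm=float(sidecar["eye_diameter_mm"]))
    nb = cfg.n_bones
    jx = np.linspace(cfg.body_length / 2, -cfg.body_length / 2, nb + 1)
    skel = Skeleton(np.column_stack([jx, np.zeros_like(jx), np.zeros_like(jx)]))

    poses = []
    for fid in sorted(pose_df.fish_id.unique()):
        seq = []
        sub = pose_df[pose_df.fish_id == fid].sort_values("frame")
        for _, r in sub.iterrows():
            yaws = np.array([float(v) for v in str(r.bone_yaws).split(";")])
            V = lbs_deform(rest, skel, yaws, np.zeros(nb))
            yaw = np.degrees(np.arctan2(r.heading_y, r.heading_x))
            heading = np.array([r.heading_x, r.heading_y, r.heading_z])
            R = rotation_about_axis(heading, r.roll_deg) \
                @ rotation_about_axis([0, 0, 1], yaw)
            V = (R @ V.T).T + np.array([r.px, r.py, r.pz])
            seq.append(FishPose(
                frame_index=int(r.frame),
                position=np.array([r.px, r.py, r.pz]),
                heading=heading / np.linalg.norm(heading), roll=float(r.roll_deg),
                bone_yaws=yaws, bone_rolls=np.zeros(nb),
                mesh_vertices=V, mesh_faces=F,
                eye_anchor_left=int(sidecar["eye_anchor_left"]),
                eye_anchor_right=int(sidecar["eye_anchor_right"]),
                eye_diameter=float(sidecar["eye_diameter_mm"]),
                eye_normal_left=np.asarray(sidecar["eye_normal_left"]),
                eye_normal_right=np.asarray(sidecar["eye_normal_right"]),
            ))
        poses.append(seq)
    return LoadedScene(config=cfg, seed=int(sidecar.get("seed", 0)),
                       poses=poses, cameras=cameras, truth=truth,
                       frame_dir=d / "frames_side")


def pair_frames_from_scene(scene: SynthScene, eyetrack: pd.DataFrame,
                           convention: str = "right-positive") -> pd.DataFrame:
    """Build the pair-frame table (follower = fish 0, leader = fish 1)."""
    rows = []
    track = eyetrack.set_index("frame") if "frame" in eyetrack else eyetrack
    for i in range(scene.config.n_frames):
        f, l = scene.poses[0][i], scene.poses[1][i]
        rel = l.position - f.position
        a = position_angle(l.position, f.position, f.heading,
                           convention=convention)
        row = dict(
            frame=i,
            position_angle_deg=a,
            front_back_x_m=float(rel[0]),
            distance_d_m=float(np.linalg.norm(rel)),
            xz_angle_deg=float(np.degrees(np.arctan2(abs(rel[2]), abs(rel[0])))),
        )
        if i in track.index:
            t = track.loc[i]
            row["eye_movement"] = float(t["eye_movement"]) \
                if not np.isnan(t.get("eye_movement", np.nan)) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def retinal_track(scene: SynthScene, condition: str = "tracked",
                  eye_side: str = "right", rng_seed: int = 0,
                  fov: float = 190.0, image_radius: float = 256.0,
                  eyetrack: pd.DataFrame | None = None) -> pd.DataFrame:
    """Neighbor retinal positions per frame under one eye condition.

    ``tracked`` uses the supplied eye track's recovered gaze (or the
    ground-truth gaze when none is given); ``static`` pins the gaze to the
    eye's optical axis; ``random`` draws a uniformly random admissible gaze
    per frame (seeded).
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    truth = scene.truth
    for i in range(scene.config.n_frames):
        follower = scene.poses[0][i]
        neighbor = scene.poses[1][i]
        n = eye_outward_normal(follower, eye_side)
        anchor = eye_anchor_position(follower, eye_side)
        origin = anchor - follower.eye_radius_m * n
        if condition == "static":
            direction = n
        elif condition == "random":
            from .synth_data import _random_pupil

            p = _random_pupil(rng, origin, follower.eye_radius_m, n,
                              scene.config.max_pupil_excursion_deg)
            direction = (p - origin) / np.linalg.norm(p - origin)
        elif eyetrack is not None:
            t = eyetrack[eyetrack.frame == i]
            if not len(t) or t.iloc[0].get("status", "ok") != "ok":
                continue
            direction = t.iloc[0][["gaze_x", "gaze_y", "gaze_z"]].to_numpy(float)
        else:
            t = truth[(truth.frame == i) & (truth.eye_side == eye_side)
                      & (truth.fish_id == 0)]
            direction = t.iloc[0][["gaze_x", "gaze_y", "gaze_z"]].to_numpy(float)
        cam = place_retina_camera(GazeRay(origin, direction), follower,
                                  fov=fov, image_radius=image_radius)
        proj = render_neighbor(cam, neighbor.mesh_vertices,
                               frame_index=i, neighbor_id=1,
                               condition=condition)
        rows.append(dict(frame=i, neighbor_id=1, condition=condition,
                         x_px=proj.x, y_px=proj.y, visible=proj.visible))
    return pd.DataFrame(rows)


def retinal_condition_stats(tracks: dict[str, pd.DataFrame],
                            sample_n: int = 1000, iterations: int = 200,
                            rng_seed: int = 0) -> dict:
    """Bootstrap spread of the neighbor's retinal position per condition.

    Returns, per condition and axis, the 200 resampled standard deviations,
    plus the fraction of iterations in which the tracked-eye spread is below
    each control's (the retinal-centering comparison).
    """
    boots = {}
    for k, (cond, df) in enumerate(tracks.items()):
        vis = df[df.visible]
        boots[cond] = {
            ax: bootstrap_std(vis[f"{ax}_px"].to_numpy(), sample_n=sample_n,
                              iterations=iterations, rng_seed=rng_seed + 7 * k + i)
            for i, ax in enumerate(("x", "y"))
        }
    out = {"sd": {c: {ax: b.mean for ax, b in axes.items()}
                  for c, axes in boots.items()}}
    if "tracked" in boots:
        for control in ("static", "random"):
            if control not in boots:
                continue
            for ax in ("x", "y"):
                frac = float(np.mean(boots["tracked"][ax].values
                                     < boots[control][ax].values))
                out[f"tracked_below_{control}_{ax}"] = frac
    out["_boots"] = boots
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline stage; returns a manifest of outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(config)
    manifest = {"config_hash": h, "outputs": []}

    if config.stage == "validate":
        kw = dict(config.validate)
        df = run_eye_validation(kw.pop("n", 500), kw.pop("w", 120),
                                seed=config.seed, **kw)
        write_track_csv(out / "validation.csv", df, seed=config.seed, cfg_hash=h)
        summary = summarize_validation(df)
        (out / "validation_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["outputs"] += ["validation.csv", "validation_summary.json"]
        manifest["summary"] = summary
        return manifest

    # scene_e2e
    scene = synthesize_scene(SceneConfig(**config.scene), rng_seed=config.seed)
    save_scene(scene, out / "scene", frames="none")
    track = track_scene(scene, fish_id=0, eye_side=config.eye_side)
    n_bad = int((track.status != "ok").sum())
    if n_bad:
        log.warning("%d frames failed tracking and were skipped", n_bad)
    write_track_csv(out / "eyetrack.csv", track, seed=config.seed, cfg_hash=h)
    pairs = pair_frames_from_scene(scene, track, convention=config.convention)
    write_track_csv(out / "pairs.csv", pairs, seed=config.seed, cfg_hash=h)
    kept, counts = filter_leader_follower(pairs.dropna(subset=["eye_movement"]))
    stats = {"counts": counts}
    if len(kept) >= 3:
        stats["correlation"] = correlate_eye_angle(kept)
    tracks = {c: retinal_track(scene, c, eye_side=config.eye_side,
                               rng_seed=config.seed,
                               eyetrack=track if c == "tracked" else None)
              for c in ("tracked", "static", "random")}
    for c, df in tracks.items():
        write_track_csv(out / f"retina_{c}.csv", df, seed=config.seed, cfg_hash=h)
    rstats = retinal_condition_stats(tracks, rng_seed=config.seed)
    rstats.pop("_boots")
    stats["retina"] = rstats
    if "gaze_err_deg" in track:
        stats["gaze_err_deg_median"] = float(track.gaze_err_deg.median())
    (out / "stats.json").write_text(json.dumps(stats, indent=2))
    manifest["outputs"] += ["scene", "eyetrack.csv", "pairs.csv", "stats.json"]
    manifest["stats"] = stats
    return manifest
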