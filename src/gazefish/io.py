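"""Readers/writers for the pipeline's on-disk formats and the run config.

Track tables are CSV with a commented header banner (tool version, config
hash, seed, units); meshes are OBJ/PLY via trimesh; camera models and run
configurations are YAML.  All text, all inspectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .geometry3d import CameraModel

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_camera",
    "write_camera",
    "write_track_csv",
    "read_track_csv",
    "RunConfig",
    "config_hash",
]

UNITS_BANNER = "units: meters, degrees, px origin top-left y-down"
SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a triangulated OBJ/PLY mesh -> (vertices (N,3) m, faces (M,3)).

    Raises :class:`ConfigError` naming the file on parse failure.
    """
    import trimesh

    path = Path(path)
    try:
        mesh = trimesh.load_mesh(path, process=False)
    except Exception as exc:
        raise ConfigError(f"cannot parse mesh {path}: {exc}") from exc
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=int)
    if V.size == 0 or F.size == 0:
        raise ConfigError(f"mesh {path} has no triangles")
    if F.max() >= len(V):
        raise ConfigError(f"mesh {path} has out-of-range face indices")
    return V, F


def write_mesh(path: str | Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    import trimesh

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(Path(path))


# ---------------------------------------------------------------------------
# cameras
# ---------------------------------------------------------------------------

def write_camera(path: str | Path, camera: CameraModel) -> None:
    data = {
        "focal_length_px": float(camera.focal_length),
        "principal_point": [float(x) for x in camera.principal_point],
        "rotation": [float(x) for x in camera.rotation.ravel()],  # row-major 9
        "translation": [float(x) for x in camera.translation],
        "image_size": [int(x) for x in camera.image_size],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_camera(path: str | Path) -> CameraModel:
    data = yaml.safe_load(Path(path).read_text())
    try:
        return CameraModel(
            focal_length=float(data["focal_length_px"]),
            principal_point=np.asarray(data["principal_point"], dtype=float),
            rotation=np.asarray(data["rotation"], dtype=float).reshape(3, 3),
            translation=np.asarray(data["translation"], dtype=float),
            image_size=tuple(int(x) for x in data["image_size"]),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid camera config {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------

def write_track_csv(path: str | Path, df: pd.DataFrame, *,
                    seed: int | None = None,
                    cfg_hash: str | None = None) -> None:
    """Write a track table with the commented provenance banner."""
    header = [
        f"# gazefish v{__version__} schema={SCHEMA_VERSION}",
        f"# {UNITS_BANNER}",
        f"# seed={seed} config_hash={cfg_hash}",
    ]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def read_track_csv(path: str | Path) -> pd.DataFrame:
    """Read a track table, checking the schema version in the banner."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        if f"schema={SCHEMA_VERSION}" not in first:
            raise ConfigError(f"{path}: unknown or missing schema version")
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stage`` selects what :func:`gazefish.pipeline.run_pipeline` executes;
    stage-specific parameter blocks are plain dicts validated against the
    dataclasses that consume them.  Unknown keys are rejected rather than
    ignored so typos fail loudly.
    """

    out_dir: str
    stage: str = "validate"                      # validate | scene_e2e
    seed: int = 0
    validate: dict = field(default_factory=lambda: {"n": 500, "w": 120})
    scene: dict = field(default_factory=dict)
    eye_side: str = "right"
    convention: str = "right-positive"
    log_level: str = "INFO"

    _KNOWN = {"out_dir", "stage", "seed", "validate", "scene", "eye_side",
              "convention", "log_level"}

    def __post_init__(self):
        if self.stage not in ("validate", "scene_e2e"):
            raise ConfigError(f"unknown stage '{self.stage}'")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ConfigError("seed must be an integer")
        from .synth_data import SceneConfig

        unknown = set(self.scene) - set(SceneConfig.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown scene keys: {sorted(unknown)}")
        unknown = set(self.validate) - {"n", "w", "tilt_range_deg", "noise", "blur"}
        if unknown:
            raise ConfigError(f"unknown validate keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "out_dir" not in data:
            raise ConfigError(f"{path}: out_dir is required")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(cfg: RunConfig | dict) -> str:
    """Stable short hash of a configuration, for output provenance banners.

    Where outputs land (``out_dir``) and how chatty the run is do not change
    the results, so they are excluded: equal hashes mean byte-identical
    outputs.
    """
    d = cfg.to_dict() if isinstance(cfg, RunConfig) else dict(cfg)
    d.pop("out_dir", None)
    d.pop("log_level", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
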