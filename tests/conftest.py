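import warnings

import numpy as np
import pytest

from gazefish.geometry3d import CameraModel, FishPose
from gazefish.synth_data import make_fish_mesh

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def camera():
    """Camera at the origin looking along +z, 640x480, f=1000 px."""
    return CameraModel(
        focal_length=1000.0,
        principal_point=(320.0, 240.0),
        rotation=np.eye(3),
        translation=np.zeros(3),
        image_size=(640, 480),
    )


def fish_pose_at(position, heading=(1.0, 0.0, 0.0), roll=0.0, frame=0):
    """A rigid fish pose from the procedural mesh, heading horizontal."""
    from gazefish.geometry3d import rotation_about_axis

    mesh = make_fish_mesh()
    heading = np.asarray(heading, dtype=float)
    heading = heading / np.linalg.norm(heading)
    yaw = np.degrees(np.arctan2(heading[1], heading[0]))
    R = rotation_about_axis(heading, roll) @ rotation_about_axis([0, 0, 1], yaw)
    V = (R @ mesh["vertices"].T).T + np.asarray(position, dtype=float)
    return FishPose(
        frame_index=frame,
        position=np.asarray(position, dtype=float),
        heading=heading,
        roll=roll,
        bone_yaws=np.zeros(4),
        bone_rolls=np.zeros(4),
        mesh_vertices=V,
        mesh_faces=mesh["faces"],
        eye_anchor_left=mesh["eye_anchor_left"],
        eye_anchor_right=mesh["eye_anchor_right"],
        eye_diameter=6.75,
        eye_normal_left=mesh["eye_normal_left"],
        eye_normal_right=mesh["eye_normal_right"],
    )


@pytest.fixture
def fish_pose():
    return fish_pose_at((0.0, 0.0, 2.0))
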