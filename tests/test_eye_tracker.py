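import numpy as np
import pytest

from gazefish.errors import (
    BackprojectionMissError,
    PupilNotFoundError,
    ScleraNotFoundError,
)
from gazefish.eye_tracker import (
    EyeState,
    back_project_eye,
    classify_pupil_position,
    detect_pupil,
    detect_sclera,
    gaze_from_eye,
    normalize_eye_movement,
    track_eye_in_crop,
)
from gazefish.geometry3d import (
    CameraModel,
    build_homography,
    eye_anchor_position,
    eye_outward_normal,
    project_point,
    rotation_about_axis,
)
from gazefish.synth_data import Circle, synthesize_eye_image

from conftest import fish_pose_at


def clean_eye(w=120, seed=0, **kw):
    return synthesize_eye_image(w, seed, tilt_range_deg=0.0, noise=False, **kw)


class TestDetectSclera:
    def test_clean_disk_diameter_and_center(self):
        """w=120 recipe: sclera disk of diameter 2w/3 = 80 px at center."""
        rec = clean_eye()
        c = detect_sclera(rec.image)
        assert c.diameter == pytest.approx(80.0, abs=2.0)
        assert np.hypot(c.cx - 59.5, c.cy - 59.5) < 1.0

    def test_uniform_image_raises(self):
        with pytest.raises(ScleraNotFoundError):
            detect_sclera(np.full((120, 120), 128.0))

    def test_center_error_under_one_px_over_generator(self, rng):
        errs = []
        for _ in range(200):
            rec = synthesize_eye_image(120, rng, tilt_range_deg=0.0, noise=False)
            c = detect_sclera(rec.image)
            errs.append(np.hypot(c.cx - rec.true_sclera.cx,
                                 c.cy - rec.true_sclera.cy))
        assert max(errs) < 1.0

    def test_external_mask_bypasses_thresholding(self):
        rec = clean_eye()
        yy, xx = np.mgrid[:120, :120]
        mask = (xx - 59.5) ** 2 + (yy - 59.5) ** 2 <= 40.0 ** 2
        c = detect_sclera(np.zeros((120, 120)), mask=mask)
        assert c.diameter == pytest.approx(80.0, abs=1.0)


class TestDetectPupil:
    def test_centered_pupil_subhalfpixel(self):
        """Noiseless symmetric pupil at the sclera center: error < 0.5 px."""
        img = np.full((120, 120), 128.0)
        from skimage.draw import disk

        rr, cc = disk((59.5, 59.5), 40.0)
        img[rr, cc] = 188.0
        rr, cc = disk((59.5, 59.5), 20.0)
        img[rr, cc] = 48.0
        sclera = detect_sclera(img)
        pupil = detect_pupil(img, sclera)
        assert np.hypot(pupil.cx - 59.5, pupil.cy - 59.5) < 0.5

    def test_dark_blob_outside_sclera_not_found(self):
        img = np.full((120, 120), 128.0)
        from skimage.draw import disk

        rr, cc = disk((59.5, 59.5), 30.0)
        img[rr, cc] = 188.0
        rr, cc = disk((10.0, 10.0), 6.0)
        img[rr, cc] = 20.0  # dark blob, but outside the sclera
        sclera = detect_sclera(img)
        with pytest.raises(PupilNotFoundError):
            detect_pupil(img, sclera)

    def test_generator_pupil_centers(self, rng):
        errs = []
        for _ in range(100):
            rec = synthesize_eye_image(120, rng, tilt_range_deg=0.0, noise=False)
            st = track_eye_in_crop(rec.image, 0, "left")
            errs.append(np.hypot(st.pupil.cx - rec.true_pupil.cx,
                                 st.pupil.cy - rec.true_pupil.cy))
        assert max(errs) < 0.5


def facing_camera(normal, anchor, dist=1.0, f=4000.0):
    z = -np.asarray(normal)
    x = np.cross([0.0, 0.0, 1.0], z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    C = anchor - dist * z
    return CameraModel(focal_length=f, principal_point=(500.0, 500.0),
                       rotation=R, translation=-R @ C, image_size=(1000, 1000))


class TestBackProjection:
    def _setup(self):
        pose = fish_pose_at((0.0, 0.0, 0.0))
        n = eye_outward_normal(pose, "right")
        anchor = eye_anchor_position(pose, "right")
        cam = facing_camera(n, anchor)
        # identity-like homography over a region around the eye
        uv = project_point(cam, anchor)
        q = np.array([uv + [-50, -50], uv + [50, -50],
                      uv + [50, 50], uv + [-50, 50]])
        h = build_homography(q, q)
        return pose, n, anchor, cam, h

    def test_pupil_at_sclera_center_maps_to_anchor(self):
        pose, n, anchor, cam, h = self._setup()
        uv = project_point(cam, anchor)
        st = EyeState(0, "right", sclera=Circle(*uv, 30.0),
                      pupil=Circle(*uv, 10.0))
        st = back_project_eye(st, h, pose, cam)
        assert np.linalg.norm(st.pupil_center_3d - anchor) < 1e-6

    def test_known_3d_pupil_recovered(self):
        pose, n, anchor, cam, h = self._setup()
        r = pose.eye_radius_m
        center = anchor - r * n
        axis = np.cross(n, [0, 0, 1.0])
        p_true = center + r * (rotation_about_axis(axis, 25.0) @ n)
        uv_p = project_point(cam, p_true)
        uv_c = project_point(cam, anchor)
        st = EyeState(0, "right", sclera=Circle(*uv_c, 30.0),
                      pupil=Circle(*uv_p, 10.0))
        st = back_project_eye(st, h, pose, cam)
        assert np.linalg.norm(st.pupil_center_3d - p_true) < 0.1 * r

    def test_ray_beyond_sphere_misses(self):
        pose, n, anchor, cam, h = self._setup()
        uv_far = project_point(cam, anchor) + np.array([300.0, 0.0])
        st = EyeState(0, "right", sclera=Circle(*uv_far, 30.0),
                      pupil=Circle(*uv_far, 10.0))
        with pytest.raises(BackprojectionMissError):
            back_project_eye(st, h, pose, cam)


class TestGaze:
    def test_pupil_at_center_gives_outward_normal(self):
        pose = fish_pose_at((0.0, 0.0, 0.0))
        n = eye_outward_normal(pose, "left")
        anchor = eye_anchor_position(pose, "left")
        st = EyeState(0, "left", pupil_center_3d=anchor)
        g = gaze_from_eye(st, pose)
        assert np.allclose(g.direction, n, atol=1e-9)
        # origin is the retina center, one eye radius beneath the anchor
        assert np.allclose(g.origin, anchor - pose.eye_radius_m * n)

    @pytest.mark.parametrize("arc_deg", [30.0, 5.0, 75.0])
    def test_arc_displacement_equals_gaze_angle(self, arc_deg):
        pose = fish_pose_at((0.0, 0.0, 0.0))
        n = eye_outward_normal(pose, "left")
        anchor = eye_anchor_position(pose, "left")
        r = pose.eye_radius_m
        center = anchor - r * n
        axis = np.cross(n, [0, 0, 1.0])
        p = center + r * (rotation_about_axis(axis, arc_deg) @ n)
        g = gaze_from_eye(EyeState(0, "left", pupil_center_3d=p), pose)
        ang = np.degrees(np.arccos(np.clip(np.dot(g.direction, n), -1, 1)))
        assert ang == pytest.approx(arc_deg, abs=1e-6)

    def test_random_placements_match_spherical_oracle(self, rng):
        """Gaze angle == pupil angular displacement from sphere geometry."""
        pose = fish_pose_at((0.0, 0.0, 0.0))
        n = eye_outward_normal(pose, "right")
        anchor = eye_anchor_position(pose, "right")
        r = pose.eye_radius_m
        center = anchor - r * n
        worst = 0.0
        for _ in range(1000):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = center + r * v
            g = gaze_from_eye(EyeState(0, "right", pupil_center_3d=p), pose)
            got = np.degrees(np.arccos(np.clip(np.dot(g.direction, n), -1, 1)))
            # oracle: central angle from the chord length anchor<->pupil
            chord = np.linalg.norm(p - anchor)
            want = np.degrees(2 * np.arcsin(np.clip(chord / (2 * r), 0, 1)))
            worst = max(worst, abs(got - want))
        assert worst < 1e-9


class TestNormalizedMovement:
    def _state(self, eye_side, pupil_center):
        return EyeState(0, eye_side,
                        sclera=Circle(60.0, 60.0, 80.0),
                        pupil=Circle(*pupil_center, 20.0))

    def test_centered_pupil_is_zero(self):
        assert normalize_eye_movement(self._state("left", (60.0, 60.0))) == 0.0

    def test_left_eye_anterior_half_radius_is_quarter(self):
        # +x in the rectified crop is the anterior direction
        assert normalize_eye_movement(
            self._state("left", (80.0, 60.0))) == pytest.approx(0.25)

    def test_right_eye_sign_flips(self):
        assert normalize_eye_movement(
            self._state("right", (80.0, 60.0))) == pytest.approx(-0.25)

    def test_antisymmetric_under_mirror(self, rng):
        for _ in range(20):
            dx, dy = rng.uniform(-15, 15, 2)
            a = normalize_eye_movement(self._state("left", (60 + dx, 60 + dy)))
            b = normalize_eye_movement(self._state("left", (60 - dx, 60 + dy)))
            assert a == pytest.approx(-b)

    def test_generator_offset_recovered(self, rng):
        for _ in range(30):
            rec = synthesize_eye_image(120, rng)
            from gazefish.geometry3d import warp_image

            rect = warp_image(rec.image, rec.tilt_homography.inverse,
                              (120, 120), cval=128.0)
            st = track_eye_in_crop(rect, 0, "left")
            got = st.normalized_offset
            assert np.linalg.norm(got - rec.true_offset) < 0.02


class TestClassification:
    def test_center_and_edge(self):
        st = EyeState(0, "left", normalized_offset=np.zeros(2))
        assert classify_pupil_position(st) == "center"
        st = EyeState(0, "left", normalized_offset=np.array([0.3, 0.0]))
        assert classify_pupil_position(st, edge_threshold=0.20) == "edge"

    def test_split_matches_brute_force_count(self, rng):
        states = [EyeState(0, "left",
                           normalized_offset=rng.uniform(-0.4, 0.4, 2))
                  for _ in range(500)]
        labels = [classify_pupil_position(s, 0.2) for s in states]
        brute = sum(np.linalg.norm(s.normalized_offset) > 0.2 for s in states)
        assert labels.count("edge") == brute
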