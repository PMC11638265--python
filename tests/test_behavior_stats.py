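import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazefish.behavior_stats import (
    bootstrap_regression,
    bootstrap_std,
    correlate_eye_angle,
    filter_leader_follower,
    filter_recording_frames,
    position_angle,
)
from gazefish.errors import (
    CoincidentFishError,
    DegenerateCorrelationError,
    EmptyStratumError,
)


def pair_table(**cols):
    n = max(len(np.atleast_1d(v)) for v in cols.values())
    base = dict(frame=np.arange(n), position_angle_deg=0.0, front_back_x_m=0.3,
                distance_d_m=0.35, xz_angle_deg=0.0, eye_movement=0.0,
                retinal_x=0.0, retinal_y=0.0)
    base.update(cols)
    return pd.DataFrame(base)


class TestPositionAngle:
    def test_leader_dead_ahead_is_zero(self):
        a = position_angle([1.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0])
        assert a == pytest.approx(0.0)

    def test_leader_on_right_is_plus_90(self):
        # heading +x, up +z: right is -y
        a = position_angle([0.0, -1.0, 0], [0.0, 0, 0], [1.0, 0, 0])
        assert a == pytest.approx(90.0)

    def test_convention_flag_flips_sign(self):
        a = position_angle([0.0, -1.0, 0], [0.0, 0, 0], [1.0, 0, 0],
                           convention="left-positive")
        assert a == pytest.approx(-90.0)

    def test_vertical_offset_ignored(self):
        a = position_angle([1.0, 0, 0.5], [0.0, 0, 0], [1.0, 0, 0])
        assert a == pytest.approx(0.0)

    def test_coincident_positions_raise(self):
        with pytest.raises(CoincidentFishError):
            position_angle([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [1.0, 0, 0])

    def test_matches_explicit_basis_oracle(self, rng):
        """Brute-force atan2 in an explicitly constructed local basis."""
        worst = 0.0
        for _ in range(1000):
            f = rng.normal(size=3)
            h = rng.normal(size=3)
            h[2] = 0.3 * h[2]  # keep heading away from vertical
            h /= np.linalg.norm(h)
            l = f + rng.normal(size=3)
            got = position_angle(l, f, h)
            # oracle: orthonormal basis built by Gram-Schmidt from scratch
            up = np.array([0.0, 0.0, 1.0])
            up = up - (up @ h) * h
            up /= np.linalg.norm(up)
            right = np.cross(h, up)
            rel = l - f
            want = np.degrees(np.arctan2(rel @ right, rel @ h))
            worst = max(worst, abs(got - want))
        assert worst < 1e-9


class TestRecordingFilter:
    def test_xz_angle_41_excluded(self):
        df = pair_table(xz_angle_deg=np.r_[np.zeros(80), [41.0], np.zeros(80)])
        segs = filter_recording_frames(df)
        assert len(segs) == 2
        assert all(len(s) >= 40 for s in segs)

    def test_short_run_dropped(self):
        df = pair_table(xz_angle_deg=np.r_[np.zeros(39), [50.0], np.zeros(45)])
        segs = filter_recording_frames(df)
        assert len(segs) == 1 and len(segs[0]) == 45

    def test_all_passing_single_segment(self):
        df = pair_table(xz_angle_deg=np.zeros(60))
        segs = filter_recording_frames(df)
        assert len(segs) == 1 and len(segs[0]) == 60

    def test_close_x_distance_excluded(self):
        df = pair_table(front_back_x_m=np.r_[np.full(50, 0.3), np.full(50, 0.15)])
        segs = filter_recording_frames(df)
        assert len(segs) == 1 and len(segs[0]) == 50

    def test_idempotent(self):
        df = pair_table(xz_angle_deg=np.r_[np.zeros(80), [41.0], np.zeros(80)])
        segs = filter_recording_frames(df)
        for s in segs:
            again = filter_recording_frames(s)
            assert len(again) == 1
            pd.testing.assert_frame_equal(again[0], s)


class TestLeaderFollowerFilter:
    def test_strict_boundaries(self):
        df = pair_table(position_angle_deg=[39.0, 40.0, -39.9],
                        front_back_x_m=[0.3, 0.3, 0.39],
                        distance_d_m=[0.40, 0.40, 0.449])
        kept, counts = filter_leader_follower(df)
        assert list(kept.frame) == [0, 2]
        assert counts["n"] == 2
        assert counts["n_positive_a"] == 1 and counts["n_negative_a"] == 1

    def test_kept_count_matches_brute_force(self, rng):
        df = pair_table(position_angle_deg=rng.uniform(-80, 80, 500),
                        front_back_x_m=rng.uniform(-0.6, 0.6, 500),
                        distance_d_m=rng.uniform(0.0, 0.8, 500))
        df.distance_d_m = np.maximum(df.distance_d_m, df.front_back_x_m.abs())
        kept, counts = filter_leader_follower(df)
        brute = sum((abs(r.position_angle_deg) < 40)
                    and (abs(r.front_back_x_m) < 0.4)
                    and (r.distance_d_m < 0.45) for r in df.itertuples())
        assert counts["n"] == brute

    def test_idempotent(self, rng):
        df = pair_table(position_angle_deg=rng.uniform(-80, 80, 200))
        once, _ = filter_leader_follower(df)
        twice, _ = filter_leader_follower(once)
        pd.testing.assert_frame_equal(once, twice)


class TestCorrelation:
    def test_exact_negative_line(self):
        df = pair_table(position_angle_deg=np.linspace(-30, 30, 20))
        df["eye_movement"] = -0.004 * df.position_angle_deg - 0.1
        res = correlate_eye_angle(df)
        assert res["r"] == pytest.approx(-1.0)
        assert res["slope"] == pytest.approx(-0.004)
        assert res["intercept"] == pytest.approx(-0.1)

    def test_independent_variables_near_zero(self, rng):
        df = pair_table(position_angle_deg=rng.uniform(-40, 40, 10_000),
                        eye_movement=rng.uniform(-0.4, 0.4, 10_000))
        assert abs(correlate_eye_angle(df)["r"]) < 0.05

    def test_generative_r_recovered(self, rng):
        """Population r = -0.7 by construction; estimate within +/-0.05."""
        slope = -0.002
        var_a = 80.0 ** 2 / 12.0
        sigma = np.sqrt(slope ** 2 * var_a * (1 - 0.7 ** 2) / 0.7 ** 2)
        for _ in range(3):
            a = rng.uniform(-40, 40, 10_000)
            x = slope * a + rng.normal(scale=sigma, size=a.size)
            df = pair_table(position_angle_deg=a, eye_movement=x)
            assert correlate_eye_angle(df)["r"] == pytest.approx(-0.7, abs=0.05)

    def test_zero_variance_rejected(self):
        df = pair_table(position_angle_deg=np.ones(10))
        with pytest.raises(DegenerateCorrelationError):
            correlate_eye_angle(df)


class TestBootstrapRegression:
    def test_noiseless_line_zero_sd(self):
        a = np.linspace(-30, 30, 200)
        df = pair_table(position_angle_deg=a, eye_movement=0.003 * a + 0.05,
                        frame=np.arange(200))
        res = bootstrap_regression(df, n_left=100, n_right=100, iterations=50)
        assert res["slope"].sd == pytest.approx(0.0, abs=1e-12)
        assert res["slope"].mean == pytest.approx(0.003)
        assert res["intercept"].mean == pytest.approx(0.05)

    def test_determinism(self, rng):
        df = pair_table(position_angle_deg=rng.uniform(-40, 40, 500),
                        eye_movement=rng.uniform(-0.4, 0.4, 500))
        a = bootstrap_regression(df, rng_seed=9)
        b = bootstrap_regression(df, rng_seed=9)
        assert np.array_equal(a["slope"].values, b["slope"].values)
        assert len(a["slope"].values) == 200

    def test_recovery_within_two_sd(self, rng):
        a = rng.uniform(-40, 40, 5000)
        x = -0.002 * a + rng.normal(scale=0.05, size=a.size)
        df = pair_table(position_angle_deg=a, eye_movement=x,
                        frame=np.arange(5000))
        res = bootstrap_regression(df, rng_seed=1)
        assert abs(res["slope"].mean - (-0.002)) < 2 * res["slope"].sd + 1e-4

    def test_empty_stratum_raises(self):
        df = pair_table(position_angle_deg=np.linspace(-30, 30, 50),
                        eye_movement=np.full(50, 0.2))  # no x < 0 stratum
        with pytest.raises(EmptyStratumError):
            bootstrap_regression(df)

    def test_strata_on_angle_option(self, rng):
        df = pair_table(position_angle_deg=rng.uniform(-40, 40, 300),
                        eye_movement=np.full(300, 0.1) + rng.normal(0, .01, 300))
        res = bootstrap_regression(df, strata_on="a", rng_seed=0)
        assert len(res["slope"].values) == 200

    def test_stratified_matches_unstratified_when_independent(self, rng):
        """With x independent of a, stratifying on x leaves the slope
        distribution unchanged (KS distance < 0.1)."""
        a = rng.uniform(-40, 40, 4000)
        x = rng.normal(scale=0.1, size=4000)  # symmetric about 0
        df = pair_table(position_angle_deg=a, eye_movement=x,
                        frame=np.arange(4000))
        strat = bootstrap_regression(df, rng_seed=3)["slope"].values
        # unstratified oracle: plain 6000-point resamples
        rng2 = np.random.default_rng(99)
        plain = np.empty(200)
        for i in range(200):
            idx = rng2.choice(4000, 6000, replace=True)
            plain[i] = np.polyfit(a[idx], x[idx], 1)[0]
        ks = sps.ks_2samp(strat, plain).statistic
        assert ks < 0.1


class TestBootstrapStd:
    def test_identical_values_zero(self):
        res = bootstrap_std(np.full(100, 3.14), rng_seed=0)
        assert np.all(res.values == 0.0)

    def test_normal_data_recovers_sigma(self, rng):
        v = rng.normal(scale=2.5, size=100_000)
        res = bootstrap_std(v, rng_seed=1)
        assert res.mean == pytest.approx(2.5, rel=0.05)

    def test_determinism(self, rng):
        v = rng.normal(size=500)
        a = bootstrap_std(v, rng_seed=4)
        b = bootstrap_std(v, rng_seed=4)
        assert np.array_equal(a.values, b.values)
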