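"""Leader-follower geometry, frame filters, and bootstrap statistics.

Two filter stages mirror the recording protocol and the schooling analysis:

* recording filter — drop frames where the two-fish angle in the x-z plane
  exceeds 40 degrees or the x-axis separation is under 0.2 m (one body
  length), split the survivors at gaps, and keep only segments of at least
  40 consecutive frames;
* leader-follower filter — keep frames with position angle |a| < 40 deg,
  front-back distance |x| < 0.4 m and pairwise distance d < 0.45 m
  (all strict).

The position angle a is the signed horizontal bearing of the leader in the
follower's local frame.  Sign convention is configurable: the default makes
a positive when the leader is on the follower's RIGHT ('right-positive');
pass ``convention='left-positive'`` to flip.

Bootstraps follow the study protocol: the eye-movement regression resamples
3000 points from each side stratum (200 iterations of 6000-point OLS), and
positional spread is summarized by 200 resampled standard deviations of
1000 points per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CoincidentFishError,
    DegenerateCorrelationError,
    EmptyStratumError,
)

__all__ = [
    "PAIR_FRAME_COLUMNS",
    "BootstrapResult",
    "position_angle",
    "filter_recording_frames",
    "filter_leader_follower",
    "correlate_eye_angle",
    "bootstrap_regression",
    "bootstrap_std",
]

#: canonical pair-frame table columns
PAIR_FRAME_COLUMNS = [
    "frame", "position_angle_deg", "front_back_x_m", "distance_d_m",
    "xz_angle_deg", "eye_movement", "retinal_x", "retinal_y",
]


@dataclass
class BootstrapResult:
    """Per-iteration bootstrap values of one statistic, with mean and sd."""

    statistic: str
    values: np.ndarray
    seed: int | None = None
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


def position_angle(
    leader_pos: np.ndarray,
    follower_pos: np.ndarray,
    follower_heading: np.ndarray,
    follower_up: np.ndarray = (0.0, 0.0, 1.0),
    convention: str = "right-positive",
) -> float:
    """Signed horizontal-plane bearing of the leader in the follower's frame.

    The leader offset is projected onto the plane spanned by the follower's
    heading and right axis (orthogonal to ``follower_up``); 0 deg is dead
    ahead, +/-180 behind.  Raises :class:`CoincidentFishError` on coincident
    positions.
    """
    lp = np.asarray(leader_pos, dtype=float)
    fp = np.asarray(follower_pos, dtype=float)
    h = np.asarray(follower_heading, dtype=float)
    h = h / np.linalg.norm(h)
    up = np.asarray(follower_up, dtype=float)
    rel = lp - fp
    if np.linalg.norm(rel) < 1e-12:
        raise CoincidentFishError("leader and follower coincide")
    up = up - np.dot(up, h) * h
    up = up / np.linalg.norm(up)
    right = np.cross(h, up)
    a = np.degrees(np.arctan2(np.dot(rel, right), np.dot(rel, h)))
    if convention == "left-positive":
        a = -a
    elif convention != "right-positive":
        raise ValueError("convention must be 'right-positive' or 'left-positive'")
    return float(a)


def filter_recording_frames(
    pair_frames: pd.DataFrame,
    max_xz_angle_deg: float = 40.0,
    min_x_distance_m: float = 0.2,
    min_segment_frames: int = 40,
) -> list[pd.DataFrame]:
    """Apply the recording-quality filter and segment the survivors.

    Frames with ``xz_angle_deg > 40`` (fish at very different heights) or
    ``|front_back_x_m| < 0.2`` (leading fish occluding the follower's head)
    are dropped; the remainder is split wherever consecutive frame indices
    gap, and segments shorter than ``min_segment_frames`` are discarded.
    Idempotent: filtering a filtered segment returns it unchanged.
    """
    df = pair_frames.sort_values("frame")
    keep = (df["xz_angle_deg"] <= max_xz_angle_deg) & \
           (df["front_back_x_m"].abs() >= min_x_distance_m)
    df = df[keep]
    if df.empty:
        return []
    breaks = np.flatnonzero(np.diff(df["frame"].to_numpy()) != 1)
    segments = np.split(np.arange(len(df)), breaks + 1)
    return [df.iloc[idx].reset_index(drop=True) for idx in segments
            if len(idx) >= min_segment_frames]


def filter_leader_follower(
    pair_frames: pd.DataFrame,
    max_angle_deg: float = 40.0,
    max_front_back_m: float = 0.4,
    max_distance_m: float = 0.45,
) -> tuple[pd.DataFrame, dict]:
    """Keep schooling frames: |a| < 40 deg, |x| < 0.4 m, d < 0.45 m (strict).

    Returns the surviving subset plus per-side counts
    ``{'n': ..., 'n_positive_a': ..., 'n_negative_a': ...}``.
    """
    df = pair_frames
    keep = (df["position_angle_deg"].abs() < max_angle_deg) & \
           (df["front_back_x_m"].abs() < max_front_back_m) & \
           (df["distance_d_m"] < max_distance_m)
    out = df[keep].reset_index(drop=True)
    counts = {
        "n": int(len(out)),
        "n_positive_a": int((out["position_angle_deg"] > 0).sum()),
        "n_negative_a": int((out["position_angle_deg"] < 0).sum()),
    }
    return out, counts


def correlate_eye_angle(pairs: pd.DataFrame) -> dict:
    """Pearson r and OLS line of eye movement on position angle.

    Returns ``{'r', 'p_value', 'slope', 'intercept', 'n'}``.  Raises
    :class:`DegenerateCorrelationError` on fewer than 3 frames or zero
    variance in either variable.
    """
    x = pairs["position_angle_deg"].to_numpy(dtype=float)
    y = pairs["eye_movement"].to_numpy(dtype=float)
    if len(x) < 3:
        raise DegenerateCorrelationError("need at least 3 frames")
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        raise DegenerateCorrelationError("zero variance")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": float(r), "p_value": float(p), "slope": float(slope),
            "intercept": float(intercept), "n": int(len(x))}


def bootstrap_regression(
    pairs: pd.DataFrame,
    n_left: int = 3000,
    n_right: int = 3000,
    iterations: int = 200,
    rng_seed: int = 0,
    strata_on: str = "x",
) -> dict[str, BootstrapResult]:
    """Stratified bootstrap of the eye-movement-vs-angle regression.

    Each iteration resamples (with replacement) ``n_left`` frames from the
    left stratum and ``n_right`` from the right, then fits OLS on the pooled
    batch.  Strata split on the eye-movement variable x (x < 0 vs x >= 0) by
    default; ``strata_on='a'`` splits on the position angle instead, which
    matches the left/right leader asymmetry the stratification compensates.

    Returns BootstrapResults for 'slope' and 'intercept'.
    """
    if strata_on == "x":
        sv = pairs["eye_movement"].to_numpy(dtype=float)
    elif strata_on == "a":
        sv = pairs["position_angle_deg"].to_numpy(dtype=float)
    else:
        raise ValueError("strata_on must be 'x' or 'a'")
    x = pairs["position_angle_deg"].to_numpy(dtype=float)
    y = pairs["eye_movement"].to_numpy(dtype=float)
    left = np.flatnonzero(sv < 0)
    right = np.flatnonzero(sv >= 0)
    if len(left) == 0 or len(right) == 0:
        raise EmptyStratumError("a bootstrap stratum is empty")
    rng = np.random.default_rng(rng_seed)
    slopes = np.empty(iterations)
    intercepts = np.empty(iterations)
    for i in range(iterations):
        idx = np.concatenate([rng.choice(left, n_left, replace=True),
                              rng.choice(right, n_right, replace=True)])
        slopes[i], intercepts[i] = np.polyfit(x[idx], y[idx], 1)
    return {
        "slope": BootstrapResult("slope", slopes, seed=rng_seed),
        "intercept": BootstrapResult("intercept", intercepts, seed=rng_seed),
    }


def bootstrap_std(
    values: np.ndarray,
    sample_n: int = 1000,
    iterations: int = 200,
    rng_seed: int = 0,
) -> BootstrapResult:
    """Bootstrap distribution of the standard deviation of ``values``.

    Each iteration draws ``sample_n`` points with replacement and records
    their standard deviation; applied per axis by callers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    rng = np.random.default_rng(rng_seed)
    out = np.empty(iterations)
    for i in range(iterations):
        out[i] = rng.choice(v, sample_n, replace=True).std()
    return BootstrapResult("std", out, seed=rng_seed)
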