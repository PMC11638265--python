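"""Domain-specific exceptions.

Every recoverable per-frame failure has its own type so pipeline code can
log-and-skip frames without masking programming errors.
"""


class GazefishError(Exception):
    """Base class for all gazefish errors."""


class BehindCameraError(GazefishError):
    """A 3D point has non-positive depth in the camera frame."""


class DegenerateCorrespondenceError(GazefishError):
    """Homography correspondence is degenerate (collinear points / singular H)."""


class EyeOccludedError(GazefishError):
    """The requested eye faces away from the camera; the frame is skipped."""


class ScleraNotFoundError(GazefishError):
    """No bright connected component qualifies as the sclera."""


class PupilNotFoundError(GazefishError):
    """No dark blob found inside the sclera circle."""


class BackprojectionMissError(GazefishError):
    """The back-projected pixel ray misses the eye sphere."""


class DegenerateGazeError(GazefishError):
    """Gaze direction has (near-)zero length."""


class PitchForbiddenError(GazefishError):
    """A skeleton bone was asked to pitch; fish bend only in yaw (+ slight roll)."""


class OutOfArenaError(GazefishError):
    """A synthetic trajectory leaves the test arena volume."""


class CoincidentFishError(GazefishError):
    """Leader and follower positions coincide; bearing undefined."""


class DegenerateCorrelationError(GazefishError):
    """Zero variance in one of the correlated variables."""


class EmptyStratumError(GazefishError):
    """A bootstrap stratum contains no samples."""


class WTooSmallError(GazefishError):
    """Synthetic eye-image side length too small for the derived kernels/radii."""


class ConfigError(GazefishError):
    """Invalid or inconsistent run configuration."""
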