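"""Exception hierarchy for liftsim."""


class LiftsimError(Exception):
    """Base class for all liftsim errors."""


class ConfigError(LiftsimError):
    """Invalid configuration value."""


class OutOfWorkspaceError(LiftsimError):
    """A kinematic target is unreachable by the chain."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class GapError(LiftsimError):
    """Marker gap that cannot be filled (leading/trailing or all-invalid)."""


class TimelineError(LiftsimError):
    """Time supports of two series do not overlap or are misaligned."""


class PoseEstimationError(LiftsimError):
    """Too few or degenerate markers for rigid pose estimation."""


class FrameTagError(LiftsimError):
    """A force record is expressed in the wrong coordinate frame."""


class EventDetectionError(LiftsimError):
    """Grip event detection failed (no extrema, odd parity, ...)."""


class InfeasibleFrameError(LiftsimError):
    """Static optimization infeasible at a frame/joint."""

    def __init__(self, message: str, frame: int | None = None, joint: str | None = None):
        super().__init__(message)
        self.frame = frame
        self.joint = joint


class FileFormatError(LiftsimError):
    """Malformed TRC/MOT/config file."""
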