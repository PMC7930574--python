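"""Exception types shared across the package."""


class JudoperfError(Exception):
    """Base class for package-specific failures."""


class DesignError(JudoperfError, ValueError):
    """Invalid study-design or simulator configuration."""


class NoOnsetError(JudoperfError):
    """No sustained deviation from the gyro baseline was found."""


class LandmarkNotFoundError(JudoperfError):
    """A kinematic landmark could not be located.

    Parameters
    ----------
    message : str
    found : int, optional
        Number of qualifying candidates that *were* found (peak search).
    stage : str, optional
        Extraction stage that failed (``"onset"``, ``"peaks"``,
        ``"inflection"``, ``"ordering"``).
    """

    def __init__(self, message, found=None, stage=None):
        super().__init__(message)
        self.found = found
        self.stage = stage


class NoConcentricPhaseError(JudoperfError, ValueError):
    """Velocity trace contains no positive (concentric) portion."""


class FitError(JudoperfError, ValueError):
    """A regression or model fit could not be computed."""


class ProfileError(JudoperfError, ValueError):
    """A load-velocity profile quantity is undefined for these inputs."""


class ConvergenceError(JudoperfError, RuntimeError):
    """Iterative estimation failed to converge."""

    def __init__(self, message, optimizer_message=None):
        super().__init__(message)
        self.optimizer_message = optimizer_message


class DegenerateDataError(JudoperfError, ValueError):
    """Data carry no usable variation for the requested analysis."""
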