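"""Exception hierarchy shared by all suaseg modules."""


class SuasegError(Exception):
    """Base class for all suaseg errors."""


class InvalidInputError(SuasegError, ValueError):
    """Raised when array inputs violate a precondition (shape, range, NaN)."""


class InvalidConfigError(SuasegError, ValueError):
    """Raised when a configuration object is internally inconsistent."""


class CalibrationError(SuasegError, ValueError):
    """Raised when threshold calibration is undefined (e.g. single-class data)."""


class GroundTruthUnavailableError(SuasegError, ValueError):
    """Raised when an operation requires a ground-truth mask that is absent."""


class UndefinedMetricError(SuasegError, ValueError):
    """Raised when a metric has no defined value for the given inputs."""


class CapacityError(SuasegError, RuntimeError):
    """Raised when synthetic blobs cannot be placed in the requested canvas."""
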