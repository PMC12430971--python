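"""Exception hierarchy shared across the toolkit."""


class ReloopError(Exception):
    """Base class for all reloop errors."""


class InputError(ReloopError, ValueError):
    """Invalid data passed to an operation (wrong shape, range, or emptiness)."""


class ConfigurationError(ReloopError, ValueError):
    """Invalid configuration (filter edges past Nyquist, missing yardstick, ...)."""


class CalibrationError(ReloopError, RuntimeError):
    """Threshold calibration failed: active and rest sEMG are indistinguishable."""


class DegenerateSampleError(InputError):
    """A paired sample with no nonzero differences; no test can be computed."""


class AlignmentError(ReloopError, ValueError):
    """Pre and post batteries do not cover the same subjects/tasks.

    ``offenders`` lists the missing (side, subject, task) entries.
    """

    def __init__(self, message: str, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders or [])


class StateError(ReloopError, RuntimeError):
    """Operation applied to an object in the wrong state (e.g. finished trial)."""
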