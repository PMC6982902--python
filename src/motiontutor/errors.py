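"""Exception hierarchy for the motion-teaching engine."""


class MotionTutorError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MotionTutorError, ValueError):
    """A value violates an operation's precondition."""


class InvalidKindError(InvalidInputError):
    """A signal of the wrong kind (accel/velocity/position) was supplied."""


class ConfigurationError(MotionTutorError):
    """Session or pipeline configuration is inconsistent or incomplete."""


class CannotSegmentError(MotionTutorError):
    """No credible motion period could be found in the signal."""


class DegenerateInputError(MotionTutorError):
    """Input collapsed to a degenerate case (e.g. all windows rejected)."""


class NoSyncError(MotionTutorError):
    """Time-point estimate is unreliable; motion error cannot be computed."""


class UndefinedStatisticError(MotionTutorError):
    """A requested statistic is undefined for the given data."""


class ParseError(MotionTutorError):
    """A file does not match its documented schema."""
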