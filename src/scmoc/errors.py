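"""Exception hierarchy for the scMoC pipeline.

Every error raised deliberately by this package derives from
:class:`ScmocError`, so callers can catch pipeline failures without
swallowing programming errors.
"""


class ScmocError(Exception):
    """Base class for all scMoC errors."""


class ValidationError(ScmocError):
    """An object violates one of its structural invariants."""


class FormatError(ScmocError):
    """An on-disk file does not match the expected format."""


class StateError(ScmocError):
    """A matrix is in the wrong processing state for an operation."""


class ParameterError(ScmocError):
    """A parameter value is outside its valid range."""


class PairingError(ScmocError):
    """The two modalities cannot be paired (e.g. no shared cells)."""


class QCError(ScmocError):
    """Quality control removed every cell."""


class CalibrationError(ScmocError):
    """The synthetic-data density calibration cannot reach its target."""


class ConfigError(ScmocError):
    """A pipeline configuration file is invalid."""
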