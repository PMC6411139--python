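"""Exception and warning types shared across the package."""


class FramepickError(Exception):
    """Base class for all framepick errors."""


class InvalidInputError(FramepickError, ValueError):
    """Raised when input data violates a precondition (bad frame, too few samples...)."""


class InvalidConfigurationError(FramepickError, ValueError):
    """Raised when a configuration value is unusable for the given data."""


class UnsupportedFormatError(FramepickError, ValueError):
    """Raised for image files the reader cannot interpret as greyscale integer frames."""


class StepwiseEliminationError(FramepickError, RuntimeError):
    """Raised when backward elimination would empty the model; user intervention is required."""


class UndefinedCorrelationError(FramepickError, ValueError):
    """Raised when a correlation is requested for a zero-variance sequence."""


class ModelFileError(FramepickError, ValueError):
    """Raised when a coefficient file cannot be parsed or fails schema validation."""


class ScoreParseError(FramepickError, ValueError):
    """Raised for malformed score/statistics CSV files; carries the offending line."""


class ConfigMismatchWarning(UserWarning):
    """Statistics were computed under a different configuration than the model was trained with."""


class DegenerateRangeWarning(UserWarning):
    """Range adjustment was requested for a set of identical scores."""


class AliasedVariableWarning(UserWarning):
    """One or more explanatory variables were dropped as linearly dependent on the others."""
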