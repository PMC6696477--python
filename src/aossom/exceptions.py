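"""Exception hierarchy for the aossom package."""


class AossomError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AossomError):
    """A recording or table file does not conform to the expected dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ParameterError(AossomError, ValueError):
    """An argument violates a documented precondition."""


class LengthError(AossomError, ValueError):
    """A series or dataset is too short (or the wrong shape) for an operation."""


class DegenerateFeatureError(AossomError, ValueError):
    """A cross-sensor feature has zero variance and cannot be normalized."""


class DegenerateInputError(AossomError, ValueError):
    """A predictor column has zero variance and cannot be scaled."""


class TrainingDivergenceError(AossomError, RuntimeError):
    """Network training produced a non-finite loss."""


class FixtureIntegrityError(AossomError, RuntimeError):
    """A packaged reference table failed its self-consistency check."""


class ModelCompatibilityError(AossomError, ValueError):
    """Feature width of the data does not match the fitted model."""
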