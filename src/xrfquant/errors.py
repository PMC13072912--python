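"""Exception hierarchy for xrfquant."""


class XrfQuantError(Exception):
    """Base class for all package errors."""


class FormatError(XrfQuantError):
    """A file is missing required columns or is otherwise malformed."""


class GridError(XrfQuantError):
    """Energy grids are non-uniform, mixed, or otherwise inconsistent."""


class ValidationError(XrfQuantError):
    """Input data violates a contract (negative counts, length mismatch...)."""


class EmptyWindowError(XrfQuantError):
    """A spectral window contains no grid channel."""


class ConfigError(XrfQuantError):
    """A configuration value is unknown or inconsistent."""


class DomainError(XrfQuantError):
    """A numeric argument is outside the mathematical domain of an operation."""


class DegenerateSpreadError(XrfQuantError):
    """A spread statistic needed as a divisor is exactly zero."""


class TrainingDivergenceError(XrfQuantError):
    """The training loss became non-finite."""


class ProcedureError(XrfQuantError):
    """A multi-step procedure reached an unrecoverable state."""
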