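"""Exception hierarchy shared across the package."""


class KrdsigError(Exception):
    """Base class for package errors."""


class ValidationError(KrdsigError, ValueError):
    """An input violates a documented invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class ParseError(KrdsigError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ScaleError(ValidationError):
    """An operation received a matrix on an incompatible value scale."""


class ConfigurationError(KrdsigError, ValueError):
    """A parameter combination is infeasible (e.g. more bins than genes)."""
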