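"""Exception hierarchy shared across the package."""


class SubtypeCEAError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SubtypeCEAError):
    """A required parameter, file or config field is missing or malformed."""


class ValidationError(SubtypeCEAError, ValueError):
    """A numeric input violates its contract (range, sum, sign, length)."""


class ScheduleLengthError(ValidationError):
    """A transition schedule is shorter than the requested horizon."""


class EstimationError(SubtypeCEAError):
    """A transition-probability estimate could not be formed (empty risk set)."""


class SchemaError(SubtypeCEAError, ValueError):
    """A CSV/registry file does not match the expected schema."""
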