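"""Exception hierarchy shared across the package."""


class ConchVisionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConchVisionError):
    """A configuration value is missing, inconsistent or unrenderable."""


class DomainError(ConchVisionError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(ConchVisionError, ValueError):
    """Input data violate a structural contract (schema, uniqueness, ...)."""
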