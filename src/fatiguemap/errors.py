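"""Exception hierarchy shared across the pipeline."""


class FatigueMapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FatigueMapError):
    """A parameter or configuration value violates a documented constraint."""


class ValidationError(FatigueMapError):
    """Input data violates a type invariant or precondition."""


class GridMismatchError(ValidationError):
    """Two volumes or masks do not share the same spatial grid."""
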