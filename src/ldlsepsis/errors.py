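"""Exception hierarchy for the LDL-sepsis pipeline."""


class LdlSepsisError(Exception):
    """Base class for all package errors."""


class SchemaError(LdlSepsisError):
    """A table is missing required columns or has unparseable values."""


class IntegrityError(LdlSepsisError):
    """Referential integrity between tables is violated."""


class ParameterError(LdlSepsisError, ValueError):
    """Invalid simulation or scoring parameters."""


class ConfigError(LdlSepsisError):
    """Invalid or incomplete code configuration."""


class FitError(LdlSepsisError):
    """A logistic model failed to converge or separated."""


class QuartileError(LdlSepsisError):
    """Quartile cut points are degenerate (an empty quartile)."""


class ValidationError(LdlSepsisError):
    """Genetic-score validation is impossible (too little overlap)."""
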