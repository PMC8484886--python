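"""Exception hierarchy shared across the package."""


class TwinlateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TwinlateError):
    """An input table is missing required columns or uses an unknown layout."""


class IntegrityError(TwinlateError):
    """Input data violate a structural invariant (duplicates, bad codes...)."""


class DomainError(TwinlateError, ValueError):
    """A value lies outside its documented domain."""


class ConfigError(TwinlateError, ValueError):
    """A configuration object is internally inconsistent."""


class EstimationError(TwinlateError):
    """A model cannot be estimated on the data supplied."""


class InestimableTermError(EstimationError):
    """A regression term carries no information (constant covariate, empty stratum)."""


class ConvergenceError(EstimationError):
    """An optimiser failed to converge; the message carries diagnostics."""
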